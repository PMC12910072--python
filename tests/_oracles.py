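"""Independent brute-force oracles for the classifier family.

Everything here is written with plain Python loops and explicit formulas,
sharing no code with the package's vectorised engines, so that agreement
between the two is a meaningful check.  The tie-break convention (fewest
mastered attributes, then binary-counting order with attribute 1 as the
low bit) is part of the method definition and is replicated here.
"""

from __future__ import annotations

import numpy as np

CLAMP = 1e-4


def all_states(n_attrs):
    out = []
    for l in range(2 ** n_attrs):
        out.append([(l >> k) & 1 for k in range(n_attrs)])
    return out


def eta_c(state, q_row):
    v = 1
    for a, qk in zip(state, q_row):
        if qk == 1 and a == 0:
            v = 0
    return v


def eta_d(state, q_row):
    for a, qk in zip(state, q_row):
        if qk == 1 and a == 1:
            return 1
    return 0


def _tie_better(cand, best, tol=1e-9):
    """cand/best are (distance, level, index) triples."""
    dc, lc, ic = cand
    db, lb, ib = best
    eps = tol * (1.0 + min(abs(dc), abs(db)))
    if dc < db - eps:
        return True
    if abs(dc - db) <= eps and (lc, ic) < (lb, ib):
        return True
    return False


def brute_npc(y_rows, q_rows):
    """Hamming-minimising state per examinee over all 2^K states."""
    n_attrs = len(q_rows[0])
    states = all_states(n_attrs)
    assigned = []
    for y in y_rows:
        best = (float("inf"), 0, 0)
        best_state = None
        for idx, state in enumerate(states):
            d = sum(abs(y[i] - eta_c(state, q_rows[i])) for i in range(len(q_rows)))
            cand = (float(d), sum(state), idx)
            if best_state is None or _tie_better(cand, best):
                best, best_state = cand, state
        assigned.append(best_state)
    return assigned


def grid_omega(member_rows, e_c, e_d, step=1e-4):
    """Grid-search argmin over omega in [0, 1] of the cluster residual."""
    best_w, best_d = 0.0, float("inf")
    w = 0.0
    while w <= 1.0 + step / 2:
        eta = w * e_c + (1 - w) * e_d
        d = sum((y - eta) ** 2 for y in member_rows)
        if d < best_d - 1e-15:
            best_d, best_w = d, w
        w += step
    return best_w


def _closed_omega(member_rows, e_c, e_d):
    if not member_rows or e_c == e_d:
        return 1.0
    num = sum(y - e_d for y in member_rows)
    den = len(member_rows) * (e_c - e_d)
    return min(1.0, max(0.0, num / den))


def brute_general(y_rows, q_rows, weighted=False, max_iter=100):
    """Naive GNPC/WGNPC: NPC init, closed-form clamped weights per occupied
    cluster, reassignment by (weighted) squared distance to blended ideals,
    until the assignment repeats."""
    n_items = len(q_rows)
    n_attrs = len(q_rows[0])
    states = all_states(n_attrs)

    if weighted:
        item_w = []
        for i in range(n_items):
            p = sum(y[i] for y in y_rows) / len(y_rows)
            p = min(max(p, CLAMP), 1 - CLAMP)
            item_w.append(1.0 / (p * (1 - p)))
    else:
        item_w = [1.0] * n_items

    assign = [states.index(s) for s in brute_npc(y_rows, q_rows)]
    history = {tuple(assign)}
    for _ in range(max_iter):
        # blended ideal rows: occupied clusters estimated, others conjunctive
        eta_rows = {}
        for l in set(assign):
            members = [y_rows[n] for n in range(len(y_rows)) if assign[n] == l]
            row = []
            for i in range(n_items):
                ec = eta_c(states[l], q_rows[i])
                ed = eta_d(states[l], q_rows[i])
                w = _closed_omega([m[i] for m in members], ec, ed)
                row.append(w * ec + (1 - w) * ed)
            eta_rows[l] = row

        new_assign = []
        for y in y_rows:
            best = (float("inf"), 0, 0)
            best_l = None
            for idx, state in enumerate(states):
                if idx in eta_rows:
                    row = eta_rows[idx]
                else:
                    row = [eta_c(state, q_rows[i]) for i in range(n_items)]
                d = sum(item_w[i] * (y[i] - row[i]) ** 2 for i in range(n_items))
                cand = (d, sum(state), idx)
                if best_l is None or _tie_better(cand, best):
                    best, best_l = cand, idx
            new_assign.append(best_l)
        if new_assign == assign:
            break
        assign = new_assign
        if tuple(assign) in history:
            break
        history.add(tuple(assign))
    return [states[l] for l in assign]


def manual_alpha(rows):
    """Cronbach's alpha by explicit spreadsheet-style sums (N-1 variances)."""
    n = len(rows)
    i = len(rows[0])

    def var(xs):
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)

    item_vars = [var([rows[r][c] for r in range(n)]) for c in range(i)]
    totals = [sum(row) for row in rows]
    return i / (i - 1) * (1 - sum(item_vars) / var(totals))
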