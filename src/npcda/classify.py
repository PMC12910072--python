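"""Nonparametric knowledge-state classifiers: NPC, GNPC, WGNPC.

Each examinee is assigned the candidate knowledge state whose ideal
response pattern is closest to the examinee's observed responses:

* **NPC** minimises the Hamming distance to the *conjunctive* IRPs
  (for binary vectors this equals the squared Euclidean distance).
* **GNPC** blends conjunctive and disjunctive ideals per state and item,
  ``eta_w = omega * eta_c + (1 - omega) * eta_d``, estimating each omega in
  closed form as the clamped least-squares minimiser of the within-cluster
  residual, and iterates: assign -> re-estimate weights -> reassign by
  squared distance, until the membership partition repeats.
* **WGNPC** uses the same iteration but scores candidate states with a
  variance-weighted squared distance, each item weighted by
  ``1 / (p_i * (1 - p_i))`` where ``p_i`` is the item's passing rate
  (clamped away from 0 and 1 by 0.0001).

Degenerate cells are handled by convention: where the conjunctive and
disjunctive ideals coincide (e.g. single-attribute items) the weight is set
to 1 (its value is immaterial), and empty clusters also use omega = 1 so
that unvisited states fall back to their conjunctive ideals.  Eq-style
weights can leave [0, 1] on noisy data and are clamped back, keeping the
blended ideal a valid response probability.

Ties in the distance minimisation are broken deterministically: fewest
mastered attributes first, then binary-counting order.

State spaces wider than the enumeration cap are searched per attribute
component; a component that is itself wider than the cap is searched by
seeded multi-start coordinate descent (bit flips accepted only on strict
improvement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ideal import conjunctive_table, disjunctive_table
from .matrices import QMatrix, ResponseMatrix
from .states import (
    DEFAULT_STATE_CAP,
    StateSpace,
    state_space_for,
    state_string,
    states_array,
)

__all__ = [
    "PASS_RATE_CLAMP",
    "ClassifierConfig",
    "ClassificationResult",
    "PassRates",
    "WeightTable",
    "hamming_distance",
    "weighted_distance",
    "residual_distance",
    "item_pass_rates",
    "estimate_weights",
    "npc_classify",
    "gnpc_classify",
    "wgnpc_classify",
]

PASS_RATE_CLAMP = 1e-4

_CHUNK = 1 << 14  # states scored per block in exhaustive search


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables of the iterative classifiers.

    max_iter : iteration cap for the GNPC/WGNPC scheme (the partition
        usually repeats within a handful of iterations).
    state_cap : widest component enumerated exhaustively; wider components
        fall back to coordinate descent.
    seed : seeds the random restarts of coordinate descent (the exhaustive
        path is fully deterministic and ignores it).
    n_random_starts : random restarts per examinee in coordinate descent,
        in addition to the all-zero, all-one and per-attribute-threshold
        starting states.
    """

    max_iter: int = 100
    state_cap: int = DEFAULT_STATE_CAP
    seed: int = 0
    n_random_starts: int = 5

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if not (1 <= self.state_cap <= 24):
            raise ValueError("state_cap must be in [1, 24]")


@dataclass(frozen=True)
class PassRates:
    """Per-item passing rates, clamped to [0.0001, 0.9999]."""

    p_bar: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p_bar, dtype=float)
        if np.any(p < PASS_RATE_CLAMP - 1e-12) or np.any(p > 1 - PASS_RATE_CLAMP + 1e-12):
            raise ValueError("pass rates must be pre-clamped to [0.0001, 0.9999]")
        p.setflags(write=False)
        object.__setattr__(self, "p_bar", p)

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / (self.p_bar * (1.0 - self.p_bar))


@dataclass(frozen=True)
class WeightTable:
    """Per-state, per-item weights blending conjunctive/disjunctive ideals."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if np.any(om < 0) or np.any(om > 1):
            raise ValueError("weights must lie in [0, 1]")
        om.setflags(write=False)
        object.__setattr__(self, "omega", om)


@dataclass(frozen=True)
class ClassificationResult:
    """Assigned knowledge states with per-examinee distances.

    ``states`` is the (N, K) binary matrix of assigned attribute-mastery
    vectors; ``distances`` the minimised distance for each examinee under
    the method's metric; ``iterations`` counts weight-reestimation rounds
    (0 for NPC); ``converged`` is False only when the iteration cap was hit
    before the membership partition repeated.
    """

    states: np.ndarray
    distances: np.ndarray
    method: str
    iterations: int
    converged: bool
    examinee_ids: tuple[str, ...]
    attribute_names: tuple[str, ...]
    tie_log: tuple[str, ...] = ()

    def state_strings(self) -> list[str]:
        return [state_string(s) for s in self.states]

    def memberships(self) -> dict[str, list[str]]:
        """The sets C_l: state string -> examinee ids assigned to it."""
        out: dict[str, list[str]] = {}
        for eid, s in zip(self.examinee_ids, self.state_strings()):
            out.setdefault(s, []).append(eid)
        return out

    def mastery_levels(self) -> np.ndarray:
        return self.states.sum(axis=1).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "examinee_id": list(self.examinee_ids),
                "state": self.state_strings(),
                "distance": self.distances,
                "method": self.method,
                "iterations": self.iterations,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary distances
# ---------------------------------------------------------------------------


def hamming_distance(y, eta) -> int:
    """Number of positions at which two binary vectors differ."""
    y = np.asarray(y)
    eta = np.asarray(eta)
    if y.shape != eta.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: {y.shape} vs {eta.shape}")
    if not (np.isin(y, (0, 1)).all() and np.isin(eta, (0, 1)).all()):
        raise ValueError("Hamming distance is defined for binary vectors")
    return int(np.abs(y.astype(np.int64) - eta.astype(np.int64)).sum())


def weighted_distance(y_row, eta_row, rates: PassRates) -> float:
    """Pass-rate-weighted squared distance between an ORP and a (possibly
    fractional) ideal response pattern."""
    y_row = np.asarray(y_row, dtype=float)
    eta_row = np.asarray(eta_row, dtype=float)
    if y_row.shape != eta_row.shape:
        raise ValueError(f"length mismatch: {y_row.shape} vs {eta_row.shape}")
    r = y_row - eta_row
    return float((rates.weights * r * r).sum())


def residual_distance(y: ResponseMatrix, eta_w: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Within-cluster residual d_li = sum over members of (y_ni - eta_w_li)^2.

    ``assignments`` maps each examinee to a state index (row of ``eta_w``);
    empty clusters have residual 0 (an empty sum).
    """
    entries = y.entries if hasattr(y, "entries") else np.asarray(y)
    eta_w = np.asarray(eta_w, dtype=float)
    assignments = np.asarray(assignments)
    out = np.zeros_like(eta_w)
    for l in np.unique(assignments):
        members = entries[assignments == l].astype(float)
        r = members - eta_w[l]
        out[l] = (r * r).sum(axis=0)
    return out


def item_pass_rates(y: ResponseMatrix) -> PassRates:
    """Fraction correct per item, clamped: rates of 0 or 1 are replaced by
    0.0001 and 0.9999 respectively so the variance weight stays finite."""
    entries = y.entries if hasattr(y, "entries") else np.asarray(y)
    p = entries.mean(axis=0).astype(float)
    p = np.clip(p, PASS_RATE_CLAMP, 1.0 - PASS_RATE_CLAMP)
    return PassRates(p)


# ---------------------------------------------------------------------------
# weight estimation
# ---------------------------------------------------------------------------


def _omega_row(y_members: np.ndarray, eta_c_row: np.ndarray, eta_d_row: np.ndarray) -> np.ndarray:
    """Closed-form clamped weights for one cluster (rows = member ORPs)."""
    m = y_members.shape[0]
    eta_c_row = eta_c_row.astype(np.float64)
    eta_d_row = eta_d_row.astype(np.float64)
    omega = np.ones_like(eta_c_row)
    diff = eta_c_row - eta_d_row
    defined = (diff != 0) & (m > 0)
    if m > 0 and defined.any():
        num = (y_members.astype(np.float64) - eta_d_row).sum(axis=0)
        omega[defined] = num[defined] / (m * diff[defined])
        np.clip(omega, 0.0, 1.0, out=omega)
    return omega


def estimate_weights(
    y: ResponseMatrix,
    assignments: np.ndarray,
    irp_c: np.ndarray,
    irp_d: np.ndarray,
) -> WeightTable:
    """Closed-form least-squares weights for every state x item cell.

    The weight for cluster l and item i is the within-cluster mean of
    ``(y - eta_d) / (eta_c - eta_d)``, clamped to [0, 1] — the constrained
    minimiser of the cluster's squared residual.  Conventions: cells with
    ``eta_c == eta_d`` and empty clusters get weight 1 (conjunctive ideal).
    """
    entries = y.entries if hasattr(y, "entries") else np.asarray(y)
    irp_c = np.asarray(getattr(irp_c, "eta", irp_c))
    irp_d = np.asarray(getattr(irp_d, "eta", irp_d))
    assignments = np.asarray(assignments)
    omega = np.ones_like(irp_c, dtype=np.float64)
    for l in np.unique(assignments):
        omega[l] = _omega_row(entries[assignments == l], irp_c[l], irp_d[l])
    return WeightTable(omega)


# ---------------------------------------------------------------------------
# exhaustive search engine
# ---------------------------------------------------------------------------


def _tie_eps(d: np.ndarray) -> np.ndarray:
    return 1e-9 * (1.0 + np.abs(d))


def _assign_min(
    y_entries: np.ndarray,
    q_entries: np.ndarray,
    item_w: np.ndarray,
    patched_rows: dict[int, np.ndarray] | None,
    n_states: int,
    n_attributes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each examinee the state minimising the (weighted) squared
    distance to its ideal row, chunking over states; ties broken by
    (mastery level, binary-counting index).

    ``patched_rows`` maps state index -> custom (weighted) eta row; all
    other states use their conjunctive ideal.  For binary etas and unit
    weights the squared distance equals the Hamming distance, so the same
    engine performs NPC assignment.
    """
    yf = y_entries.astype(np.float64)
    yw = yf * item_w
    y_const = (yw * yf).sum(axis=1)
    n = yf.shape[0]

    best_d = np.full(n, np.inf)
    best_key = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    best_idx = np.zeros(n, dtype=np.int64)

    k_range = np.arange(n_attributes)
    qsum = q_entries.sum(axis=1)

    for start in range(0, n_states, _CHUNK):
        stop = min(start + _CHUNK, n_states)
        idx = np.arange(start, stop, dtype=np.int64)
        chunk_states = ((idx[:, None] >> k_range) & 1).astype(np.int64)
        eta = (chunk_states @ q_entries.T.astype(np.int64) == qsum).astype(np.float64)
        if patched_rows:
            for l, row in patched_rows.items():
                if start <= l < stop:
                    eta[l - start] = row
        d = y_const[:, None] - 2.0 * (yw @ eta.T) + (item_w * eta * eta).sum(axis=1)[None, :]
        np.maximum(d, 0.0, out=d)

        levels = chunk_states.sum(axis=1)
        key = levels * np.int64(n_states) + idx
        # per-examinee best within the chunk, with tie-break on key
        dmin = d.min(axis=1, keepdims=True)
        close = d <= dmin + _tie_eps(dmin)
        keym = np.where(close, key[None, :], np.iinfo(np.int64).max)
        j = keym.argmin(axis=1)
        cand_d = d[np.arange(n), j]
        cand_key = key[j]
        cand_idx = idx[j]
        # merge with running best
        eps = _tie_eps(np.minimum(best_d, cand_d))
        better = (cand_d < best_d - eps) | (
            (np.abs(cand_d - best_d) <= eps) & (cand_key < best_key)
        )
        best_d = np.where(better, cand_d, best_d)
        best_key = np.where(better, cand_key, best_key)
        best_idx = np.where(better, cand_idx, best_idx)
    return best_idx, best_d


def _count_ties(
    y_entries: np.ndarray,
    q_entries: np.ndarray,
    item_w: np.ndarray,
    patched_rows: dict[int, np.ndarray] | None,
    n_states: int,
    n_attributes: int,
    best_d: np.ndarray,
) -> np.ndarray:
    """Number of states within tolerance of each examinee's best distance."""
    yf = y_entries.astype(np.float64)
    yw = yf * item_w
    y_const = (yw * yf).sum(axis=1)
    counts = np.zeros(yf.shape[0], dtype=np.int64)
    k_range = np.arange(n_attributes)
    qsum = q_entries.sum(axis=1)
    for start in range(0, n_states, _CHUNK):
        stop = min(start + _CHUNK, n_states)
        idx = np.arange(start, stop, dtype=np.int64)
        chunk_states = ((idx[:, None] >> k_range) & 1).astype(np.int64)
        eta = (chunk_states @ q_entries.T.astype(np.int64) == qsum).astype(np.float64)
        if patched_rows:
            for l, row in patched_rows.items():
                if start <= l < stop:
                    eta[l - start] = row
        d = y_const[:, None] - 2.0 * (yw @ eta.T) + (item_w * eta * eta).sum(axis=1)[None, :]
        counts += (d <= (best_d + _tie_eps(best_d))[:, None]).sum(axis=1)
    return counts


def _exhaustive_engine(
    y_entries: np.ndarray,
    q_entries: np.ndarray,
    method: str,
    config: ClassifierConfig,
) -> tuple[np.ndarray, np.ndarray, int, bool, np.ndarray]:
    """Run one classifier over the full 2^K space for one (sub-)design.

    Returns (assigned state indices, distances, iterations, converged,
    tie counts at the final assignment).
    """
    n_attributes = q_entries.shape[1]
    n_states = 1 << n_attributes
    ones = np.ones(q_entries.shape[0], dtype=np.float64)

    assign, dist = _assign_min(y_entries, q_entries, ones, None, n_states, n_attributes)
    if method == "npc":
        ties = _count_ties(y_entries, q_entries, ones, None, n_states, n_attributes, dist)
        return assign, dist, 0, True, ties

    item_w = item_pass_rates(y_entries).weights if method == "wgnpc" else ones

    seen = {assign.tobytes()}
    converged = False
    iterations = 0
    patched: dict[int, np.ndarray] = {}
    k_range = np.arange(n_attributes)
    for iterations in range(1, config.max_iter + 1):
        # weighted eta rows for occupied states only; empty states keep eta_c
        patched = {}
        occupied = np.unique(assign)
        occ_states = ((occupied[:, None] >> k_range) & 1).astype(np.int64)
        eta_c_occ = conjunctive_table(occ_states, q_entries).astype(np.float64)
        eta_d_occ = disjunctive_table(occ_states, q_entries).astype(np.float64)
        for j, l in enumerate(occupied):
            members = y_entries[assign == l]
            omega = _omega_row(members, eta_c_occ[j], eta_d_occ[j])
            patched[int(l)] = omega * eta_c_occ[j] + (1.0 - omega) * eta_d_occ[j]

        new_assign, dist = _assign_min(
            y_entries, q_entries, item_w, patched, n_states, n_attributes
        )
        if np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign
        b = assign.tobytes()
        if b in seen:
            converged = True  # partition repeated (cycle); stop
            break
        seen.add(b)
    ties = _count_ties(y_entries, q_entries, item_w, patched, n_states, n_attributes, dist)
    return assign, dist, iterations, converged, ties


# ---------------------------------------------------------------------------
# coordinate-descent engine for components wider than the cap
# ---------------------------------------------------------------------------


def _cd_starts(y_entries: np.ndarray, q_entries: np.ndarray, rng, n_random: int) -> np.ndarray:
    """Starting states per examinee: all-zero, all-one, an attribute-wise
    pass-rate threshold state, and seeded random states."""
    n, n_attributes = y_entries.shape[0], q_entries.shape[1]
    coverage = q_entries.sum(axis=0).astype(float)
    coverage[coverage == 0] = 1.0
    frac = (y_entries.astype(float) @ q_entries.astype(float)) / coverage
    starts = [
        np.zeros((n, n_attributes), dtype=np.uint8),
        np.ones((n, n_attributes), dtype=np.uint8),
        (frac >= 0.5).astype(np.uint8),
    ]
    for _ in range(n_random):
        starts.append(rng.integers(0, 2, size=(n, n_attributes), dtype=np.uint8))
    return np.stack(starts)  # (S, N, K)


def _cd_key(state: np.ndarray) -> tuple[int, int]:
    level = int(state.sum())
    idx = int((state.astype(object) * (2 ** np.arange(state.size, dtype=object))).sum())
    return level, idx


def _cd_search_one(
    dist_fn: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
) -> tuple[np.ndarray, float]:
    """Multi-start coordinate descent over bit flips for one examinee.

    Flips are accepted only on strict improvement, so each start terminates;
    the best local optimum wins, ties broken by (level, binary index)."""
    best_state: np.ndarray | None = None
    best_d = np.inf
    best_key: tuple[int, int] | None = None
    for s0 in starts:
        state = s0.copy()
        d = dist_fn(state)
        improved = True
        while improved:
            improved = False
            for k in range(state.size):
                state[k] ^= 1
                dc = dist_fn(state)
                if dc < d - 1e-12 * (1.0 + abs(d)):
                    d = dc
                    improved = True
                else:
                    state[k] ^= 1
        key = _cd_key(state)
        eps = 1e-9 * (1.0 + min(abs(d), abs(best_d) if np.isfinite(best_d) else abs(d)))
        if d < best_d - eps or (abs(d - best_d) <= eps and key < best_key):
            best_state, best_d, best_key = state.copy(), d, key
    assert best_state is not None
    return best_state, best_d


def _cd_engine(
    y_entries: np.ndarray,
    q_entries: np.ndarray,
    method: str,
    config: ClassifierConfig,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Approximate classifier for a component too wide to enumerate.

    Returns (assigned states (N, K), distances, iterations, converged)."""
    rng = np.random.default_rng(config.seed)
    n, n_items = y_entries.shape
    qt = q_entries.T.astype(np.int64)
    qsum = q_entries.sum(axis=1).astype(np.int64)
    starts = _cd_starts(y_entries, q_entries, rng, config.n_random_starts)
    yf = y_entries.astype(np.float64)

    def eta_c_row(state: np.ndarray) -> np.ndarray:
        return (state.astype(np.int64) @ qt == qsum).astype(np.float64)

    def eta_d_row(state: np.ndarray) -> np.ndarray:
        return (state.astype(np.int64) @ qt > 0).astype(np.float64)

    ones = np.ones(n_items, dtype=np.float64)
    item_w = item_pass_rates(y_entries).weights if method == "wgnpc" else ones

    def assign_all(weight_vec: np.ndarray, eta_lookup: dict[bytes, np.ndarray] | None):
        out = np.empty((n, q_entries.shape[1]), dtype=np.uint8)
        dists = np.empty(n)
        for i in range(n):
            yi = yf[i]

            def dist_fn(state: np.ndarray) -> float:
                row = None
                if eta_lookup is not None:
                    row = eta_lookup.get(state.tobytes())
                if row is None:
                    row = eta_c_row(state)
                r = yi - row
                return float((weight_vec * r * r).sum())

            per_starts = [starts[s, i] for s in range(starts.shape[0])]
            if eta_lookup is not None:
                per_starts.append(assign[i])  # warm start from current state
            out[i], dists[i] = _cd_search_one(dist_fn, per_starts)
        return out, dists

    assign, dist = assign_all(ones, None)  # NPC (Hamming == squared on binary)
    if method == "npc":
        return assign, dist, 0, True

    seen = {assign.tobytes()}
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        lookup: dict[bytes, np.ndarray] = {}
        keys = [assign[i].tobytes() for i in range(n)]
        for key in set(keys):
            members = yf[[i for i in range(n) if keys[i] == key]]
            state = np.frombuffer(key, dtype=np.uint8)
            ec, ed = eta_c_row(state), eta_d_row(state)
            omega = _omega_row(members, ec, ed)
            lookup[key] = omega * ec + (1.0 - omega) * ed
        new_assign, dist = assign_all(item_w, lookup)
        if np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign
        b = assign.tobytes()
        if b in seen:
            converged = True
            break
        seen.add(b)
    return assign, dist, iterations, converged


# ---------------------------------------------------------------------------
# public classifiers
# ---------------------------------------------------------------------------


def _classify(
    y: ResponseMatrix,
    q: QMatrix,
    method: str,
    space: StateSpace | None,
    config: ClassifierConfig | None,
) -> ClassificationResult:
    config = config or ClassifierConfig()
    if tuple(y.item_ids) != tuple(q.item_ids):
        raise ValueError("Q-matrix and responses are not item-aligned; call align() first")
    if space is None:
        space = state_space_for(q, cap=config.state_cap)
    if space.n_attributes != q.n_attributes:
        raise ValueError("state space and Q-matrix disagree on K")

    n, n_attributes = y.n_examinees, q.n_attributes
    tie_log: list[str] = []

    if space.mode == "exhaustive":
        assign, dist, iterations, converged, ties = _exhaustive_engine(
            y.entries, q.entries, method, config
        )
        alpha = ((assign[:, None] >> np.arange(n_attributes)) & 1).astype(np.uint8)
        for i in np.flatnonzero(ties > 1):
            tie_log.append(
                f"examinee {y.examinee_ids[i]!r}: {int(ties[i])} states tied at "
                "minimum distance; parsimony tie-break applied"
            )
    else:
        alpha = np.zeros((n, n_attributes), dtype=np.uint8)
        dist = np.zeros(n)
        iterations, converged = 0, True
        for comp in space.components:
            sub_q = q.entries[np.ix_(list(comp.items), list(comp.attributes))]
            sub_y = y.entries[:, list(comp.items)]
            if len(comp.attributes) <= config.state_cap:
                a_idx, d, it, conv, _ = _exhaustive_engine(sub_y, sub_q, method, config)
                a = ((a_idx[:, None] >> np.arange(len(comp.attributes))) & 1).astype(np.uint8)
            else:
                a, d, it, conv = _cd_engine(sub_y, sub_q, method, config)
            alpha[:, list(comp.attributes)] = a
            dist += d
            iterations = max(iterations, it)
            converged = converged and conv

    return ClassificationResult(
        states=alpha,
        distances=np.asarray(dist, dtype=float),
        method=method,
        iterations=iterations,
        converged=converged,
        examinee_ids=tuple(y.examinee_ids),
        attribute_names=tuple(q.attribute_names),
        tie_log=tuple(tie_log),
    )


def npc_classify(
    y: ResponseMatrix,
    q: QMatrix,
    space: StateSpace | None = None,
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Assign each examinee the state minimising the Hamming distance
    between its ORP and the conjunctive IRP."""
    return _classify(y, q, "npc", space, config)


def gnpc_classify(
    y: ResponseMatrix,
    q: QMatrix,
    space: StateSpace | None = None,
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Iterated general nonparametric classification with per-cell weighted
    ideal responses; NPC seeds the iteration."""
    return _classify(y, q, "gnpc", space, config)


def wgnpc_classify(
    y: ResponseMatrix,
    q: QMatrix,
    space: StateSpace | None = None,
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """GNPC scored with the pass-rate variance-weighted distance
    (items with extreme passing rates count more)."""
    return _classify(y, q, "wgnpc", space, config)
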