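"""Ideal response patterns (IRPs) under condensation rules.

Given a knowledge state alpha and an item's q-vector, the ideal response is
the answer the state would produce without noise:

* conjunctive (DINA-type): correct iff *all* measured attributes are
  mastered, ``eta_c = prod_k alpha_k ** q_ik``;
* disjunctive (DINO-type): correct iff *at least one* measured attribute is
  mastered, ``eta_d = 1 - prod_k (1 - alpha_k) ** q_ik``;
* weighted: the convex blend ``eta_w = omega * eta_c + (1 - omega) * eta_d``
  with a per-state, per-item weight omega in [0, 1].

Since mastering all measured attributes implies mastering at least one,
``eta_c <= eta_d`` always, and the blend lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import StateSpace, state_string

__all__ = [
    "eta_conjunctive",
    "eta_disjunctive",
    "eta_weighted",
    "conjunctive_table",
    "disjunctive_table",
    "IrpTable",
    "build_irp_table",
]


def _check_pair(alpha, q_row):
    alpha = np.asarray(alpha)
    q_row = np.asarray(q_row)
    if alpha.shape != q_row.shape or alpha.ndim != 1:
        raise ValueError(
            f"state and q-vector lengths differ: {alpha.shape} vs {q_row.shape}"
        )
    return alpha, q_row


def eta_conjunctive(alpha, q_row) -> int:
    """1 iff the state masters every attribute the item measures."""
    alpha, q_row = _check_pair(alpha, q_row)
    return int(((alpha == 1) | (q_row == 0)).all())


def eta_disjunctive(alpha, q_row) -> int:
    """1 iff the state masters at least one measured attribute."""
    alpha, q_row = _check_pair(alpha, q_row)
    return int(((alpha == 1) & (q_row == 1)).any())


def eta_weighted(eta_c, eta_d, omega):
    """Convex blend of conjunctive and disjunctive ideals."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0) or np.any(omega > 1):
        raise ValueError("omega must lie in [0, 1]")
    out = omega * np.asarray(eta_c, dtype=float) + (1.0 - omega) * np.asarray(
        eta_d, dtype=float
    )
    return float(out) if out.ndim == 0 else out


def conjunctive_table(states: np.ndarray, q_entries: np.ndarray) -> np.ndarray:
    """(L, I) conjunctive ideal responses for every state x item."""
    q = np.asarray(q_entries, dtype=np.int64)
    s = np.asarray(states, dtype=np.int64)
    return (s @ q.T == q.sum(axis=1)).astype(np.uint8)


def disjunctive_table(states: np.ndarray, q_entries: np.ndarray) -> np.ndarray:
    """(L, I) disjunctive ideal responses for every state x item."""
    q = np.asarray(q_entries, dtype=np.int64)
    s = np.asarray(states, dtype=np.int64)
    return (s @ q.T > 0).astype(np.uint8)


@dataclass(frozen=True)
class IrpTable:
    """Ideal responses eta for every candidate state (rows) x item (columns)."""

    eta: np.ndarray
    rule: str
    states: np.ndarray
    item_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rule not in ("conjunctive", "disjunctive", "weighted"):
            raise ValueError(f"unknown condensation rule {self.rule!r}")
        eta = np.asarray(self.eta, dtype=float)
        if np.any(eta < 0) or np.any(eta > 1):
            raise ValueError("ideal responses must lie in [0, 1]")
        if self.rule != "weighted" and not np.isin(eta, (0.0, 1.0)).all():
            raise ValueError(f"{self.rule} ideal responses must be 0/1")
        object.__setattr__(self, "eta", eta)
        if self.item_ids is None:
            object.__setattr__(
                self, "item_ids", tuple(f"item{i + 1}" for i in range(eta.shape[1]))
            )

    def to_frame(self) -> pd.DataFrame:
        labels = [state_string(s) for s in self.states]
        return pd.DataFrame(
            self.eta, index=pd.Index(labels, name="state"), columns=list(self.item_ids)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_irp_table(q, space: StateSpace, rule: str = "conjunctive", weights=None) -> IrpTable:
    """IRP table for an exhaustive state space under the chosen rule.

    The weighted rule needs a per-state, per-item weight table (an (L, I)
    array or a WeightTable with an ``omega`` attribute).
    """
    if space.mode != "exhaustive":
        raise ValueError(
            "IRP tables are materialised for exhaustive spaces only; classify "
            "component-decomposed designs per component"
        )
    entries = q.entries if hasattr(q, "entries") else np.asarray(q)
    item_ids = tuple(getattr(q, "item_ids", ()) or ())
    if entries.shape[1] != space.n_attributes:
        raise ValueError("Q-matrix and state space disagree on K")
    eta_c = conjunctive_table(space.states, entries)
    if rule == "conjunctive":
        eta = eta_c.astype(float)
    elif rule == "disjunctive":
        eta = disjunctive_table(space.states, entries).astype(float)
    elif rule == "weighted":
        if weights is None:
            raise ValueError("weighted IRP table requires a weight table")
        omega = np.asarray(getattr(weights, "omega", weights), dtype=float)
        if omega.shape != eta_c.shape:
            raise ValueError(f"weight table shape {omega.shape} != {eta_c.shape}")
        eta_d = disjunctive_table(space.states, entries).astype(float)
        eta = omega * eta_c + (1.0 - omega) * eta_d
    else:
        raise ValueError(f"unknown condensation rule {rule!r}")
    return IrpTable(eta, rule, space.states, item_ids or None)
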