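"""Knowledge states and candidate state spaces.

A knowledge state is a binary vector alpha of length K: alpha_k = 1 means
the examinee has mastered attribute k.  With K attributes there are 2^K
possible states.  States are ordered in binary-counting order with
attribute 1 as the lowest bit, so state index l has
``alpha_k = (l >> k) & 1``; this ordering is the deterministic tie-break
reference used throughout the package.

Exhaustive enumeration is capped (default K = 20).  Beyond the cap the
candidate space is handled by decomposing the attributes into connected
components of the co-occurrence graph — two attributes are linked iff some
item measures both — and classifying each component separately; every item
falls entirely within one component, because an item links all the
attributes it measures pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "DEFAULT_STATE_CAP",
    "KnowledgeState",
    "Component",
    "StateSpace",
    "states_array",
    "enumerate_states",
    "attribute_components",
    "state_space_for",
    "state_string",
    "state_index",
]

DEFAULT_STATE_CAP = 20


@dataclass(frozen=True)
class KnowledgeState:
    """Binary attribute-mastery vector."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.alpha)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("knowledge state must be a non-empty 1-D vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("knowledge state entries must be 0 or 1")
        arr = arr.astype(np.uint8)
        arr.setflags(write=False)
        object.__setattr__(self, "alpha", arr)

    @property
    def mastery_level(self) -> int:
        return int(self.alpha.sum())

    def __str__(self) -> str:
        return state_string(self.alpha)


def states_array(n_attributes: int) -> np.ndarray:
    """All 2^K states as a (2^K, K) uint8 array in binary-counting order."""
    if n_attributes < 1:
        raise ValueError("need at least one attribute")
    count = 1 << n_attributes
    idx = np.arange(count, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n_attributes)) & 1).astype(np.uint8)


def state_string(alpha) -> str:
    return "".join(str(int(a)) for a in np.asarray(alpha))


def state_index(alpha) -> int:
    """Position of a state in binary-counting order (attribute 1 = low bit)."""
    alpha = np.asarray(alpha)
    return int((alpha.astype(np.int64) << np.arange(alpha.size)).sum())


@dataclass(frozen=True)
class Component:
    """A connected component of the attribute co-occurrence graph."""

    attributes: tuple[int, ...]
    items: tuple[int, ...]


@dataclass(frozen=True)
class StateSpace:
    """Candidate knowledge-state space for classification.

    ``mode`` is ``"exhaustive"`` (all 2^K states materialised in ``states``)
    or ``"component"`` (attributes partitioned into co-occurrence
    components, each searched separately).
    """

    n_attributes: int
    mode: str
    states: np.ndarray | None = None
    components: tuple[Component, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("exhaustive", "component"):
            raise ValueError(f"unknown state-space mode {self.mode!r}")
        if self.mode == "exhaustive":
            if self.states is None or self.states.shape != (
                1 << self.n_attributes,
                self.n_attributes,
            ):
                raise ValueError("exhaustive space must hold all 2^K states")
        elif self.components is None:
            raise ValueError("component space must hold its components")

    @property
    def n_states(self) -> int:
        return 1 << self.n_attributes


def enumerate_states(n_attributes: int, cap: int = DEFAULT_STATE_CAP) -> StateSpace:
    """Exhaustive state space, refused above the cap (use component mode)."""
    if n_attributes > cap:
        raise ValueError(
            f"refusing to enumerate 2^{n_attributes} states (cap {cap}); "
            "use state_space_for() for component decomposition"
        )
    return StateSpace(n_attributes, "exhaustive", states=states_array(n_attributes))


def attribute_components(q) -> tuple[Component, ...]:
    """Partition attributes into connected components of co-occurrence.

    Two attributes are linked iff some item measures both.  Each item's
    attributes form a clique, so every item belongs to exactly one
    component.  Components are ordered by their smallest attribute index.
    """
    entries = q.entries if hasattr(q, "entries") else np.asarray(q)
    adjacency = (entries.T.astype(np.int64) @ entries.astype(np.int64)) > 0
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    comps = []
    for lab in range(n_comp):
        attrs = np.flatnonzero(labels == lab)
        items = np.flatnonzero(entries[:, attrs].any(axis=1))
        comps.append(Component(tuple(int(a) for a in attrs), tuple(int(i) for i in items)))
    comps.sort(key=lambda c: c.attributes[0])
    return tuple(comps)


def state_space_for(q, cap: int = DEFAULT_STATE_CAP, mode: str | None = None) -> StateSpace:
    """Choose a state space for a Q-matrix: exhaustive if K <= cap, else
    component decomposition.  ``mode`` forces one or the other."""
    n_attributes = q.entries.shape[1] if hasattr(q, "entries") else np.asarray(q).shape[1]
    if mode is None:
        mode = "exhaustive" if n_attributes <= cap else "component"
    if mode == "exhaustive":
        return enumerate_states(n_attributes, cap=cap)
    return StateSpace(n_attributes, "component", components=attribute_components(q))
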