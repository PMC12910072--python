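"""Synthetic diagnostic-assessment data: Q-matrices, latent knowledge
states, and noisy binary responses.

The generator emulates the structure of a large single-best-answer MCQ
bank diagnosed with nonparametric classification: a heavily skewed
attribute-coverage distribution (a few subdomains measured by hundreds of
items, others by a handful), 1-3 attributes per item, latent binary
mastery states per examinee, and a slip/guess response model.  The
default noise model is DINA (conjunctive): an examinee whose state
masters all of an item's attributes answers correctly with probability
1 - slip, otherwise with probability guess.  A DINO (disjunctive) variant
is included for testing the disjunctive condensation rule.

The ``study_spec`` preset reproduces the shape of the motivating cohort:
41 examinees x 2,809 items x 22 attributes with the published per-
subdomain item counts, five-option items (guess = 0.2, chance level),
slip = 0.1, and a high mastery prevalence (0.85 per attribute,
independent Bernoulli), matching a cohort of strong examinees that
master most but not all subdomains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .ideal import conjunctive_table, disjunctive_table
from .matrices import QMatrix, ResponseMatrix

__all__ = [
    "SimulationSpec",
    "STUDY_ATTRIBUTE_COUNTS",
    "study_spec",
    "simulate_qmatrix",
    "simulate_knowledge_states",
    "simulate_responses",
    "simulate_dataset",
]

# Published per-subdomain item counts of the motivating assessment
# (2,809 items; incidences sum to 2,856, so most items are single-attribute).
STUDY_ATTRIBUTE_COUNTS: dict[str, int] = {
    "Endocrinology": 454,
    "Respiratory medicine": 330,
    "Cardiology": 304,
    "Infectious diseases": 238,
    "Gastroenterology": 227,
    "Nephrology": 211,
    "Haematology": 203,
    "Neurology": 203,
    "Rheumatology": 201,
    "Miscellaneous": 95,
    "Dermatology": 93,
    "Obs & gynae": 61,
    "Emergency medicine": 52,
    "ECG & hypertension & lipids": 48,
    "Microbiology": 44,
    "Genitourinary": 23,
    "Anaesthetics & ITU": 21,
    "Oncology": 21,
    "Liver disorders": 15,
    "Pharmacology": 6,
    "Neuroscience": 3,
    "Radiology": 3,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    ``attribute_targets`` fixes per-attribute item counts (the coverage
    skew); alternatively ``attribute_skew`` gives a power-law exponent for
    sampling weights.  ``mastery_prob`` is the per-attribute Bernoulli
    prevalence of mastery (scalar or length-K), or pass ``explicit_states``
    to fix the latent states outright.  ``generating_rule`` selects the
    DINA (conjunctive) or DINO (disjunctive) noise model.
    """

    n_examinees: int
    n_items: int
    n_attributes: int
    max_attrs_per_item: int = 3
    attribute_targets: tuple[int, ...] | None = None
    attribute_skew: float | None = None
    slip: float = 0.1
    guess: float = 0.2
    mastery_prob: float | tuple[float, ...] = 0.5
    explicit_states: tuple[tuple[int, ...], ...] | None = None
    complete: bool = True
    generating_rule: str = "conjunctive"
    attribute_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_examinees, self.n_items, self.n_attributes) < 1:
            raise ValueError("n_examinees, n_items, n_attributes must be positive")
        if self.max_attrs_per_item < 1:
            raise ValueError("max_attrs_per_item must be at least 1")
        for name in ("slip", "guess"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        probs = np.atleast_1d(np.asarray(self.mastery_prob, dtype=float))
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("mastery_prob entries must be probabilities")
        if probs.size not in (1, self.n_attributes):
            raise ValueError("mastery_prob must be scalar or length K")
        if self.generating_rule not in ("conjunctive", "disjunctive"):
            raise ValueError("generating_rule must be conjunctive or disjunctive")
        if self.attribute_targets is not None:
            targets = tuple(int(t) for t in self.attribute_targets)
            if len(targets) != self.n_attributes:
                raise ValueError("attribute_targets must have length K")
            if any(t < 1 for t in targets):
                raise ValueError("attribute_targets must be positive")
            if sum(targets) < self.n_items:
                raise ValueError(
                    "attribute_targets sum below item count: some item would "
                    "measure no attribute"
                )
            object.__setattr__(self, "attribute_targets", targets)
        if self.explicit_states is not None:
            arr = np.asarray(self.explicit_states)
            if arr.shape != (self.n_examinees, self.n_attributes) or not np.isin(
                arr, (0, 1)
            ).all():
                raise ValueError("explicit_states must be an N x K binary array")
            object.__setattr__(
                self,
                "explicit_states",
                tuple(tuple(int(v) for v in row) for row in arr),
            )
        if self.complete and self.n_items < self.n_attributes:
            raise ValueError("a complete design needs at least K items")
        if self.attribute_names is not None:
            names = tuple(str(a) for a in self.attribute_names)
            if len(names) != self.n_attributes:
                raise ValueError("attribute_names must have length K")
            object.__setattr__(self, "attribute_names", names)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("attribute_targets", "attribute_names", "explicit_states"):
            if raw.get(key) is not None:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        if isinstance(raw.get("mastery_prob"), list):
            raw["mastery_prob"] = tuple(raw["mastery_prob"])
        return cls(**raw)


def study_spec(seed: int = 0) -> SimulationSpec:
    """Preset matching the motivating assessment's shape (41 x 2809 x 22)."""
    return SimulationSpec(
        n_examinees=41,
        n_items=2809,
        n_attributes=22,
        max_attrs_per_item=3,
        attribute_targets=tuple(STUDY_ATTRIBUTE_COUNTS.values()),
        attribute_names=tuple(STUDY_ATTRIBUTE_COUNTS),
        slip=0.1,
        guess=0.2,
        mastery_prob=0.85,
        seed=seed,
    )


def _attribute_weights(spec: SimulationSpec) -> np.ndarray:
    if spec.attribute_targets is not None:
        w = np.asarray(spec.attribute_targets, dtype=float)
    elif spec.attribute_skew is not None:
        w = (np.arange(spec.n_attributes) + 1.0) ** (-float(spec.attribute_skew))
    else:
        w = np.ones(spec.n_attributes)
    return w / w.sum()


def simulate_qmatrix(spec: SimulationSpec, rng: np.random.Generator | None = None) -> QMatrix:
    """Draw a valid Q-matrix under the spec's coverage structure.

    With ``complete=True`` the first K items form an identity submatrix
    (each attribute has a pure single-attribute item), which makes the
    conjunctive IRPs pairwise distinct and the states identifiable.  With
    explicit per-attribute targets, the remaining attribute incidences are
    dealt like tokens: every remaining item receives one, then leftovers
    are placed on random items with spare capacity that do not already
    measure that attribute (unplaceable tokens are dropped, keeping column
    sums within a few counts of target).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_items, n_attrs = spec.n_items, spec.n_attributes
    q = np.zeros((n_items, n_attrs), dtype=np.int8)
    start = 0
    if spec.complete:
        q[:n_attrs, :] = np.eye(n_attrs, dtype=np.int8)
        start = n_attrs

    rest = np.arange(start, n_items)
    if rest.size:
        if spec.attribute_targets is not None:
            targets = np.asarray(spec.attribute_targets, dtype=np.int64)
            remaining = targets - q[:start].sum(axis=0)
            if np.any(remaining < 0):
                raise ValueError("attribute_targets below the identity block coverage")
            if remaining.sum() < rest.size:
                raise ValueError(
                    "attribute_targets leave fewer incidences than remaining items"
                )
            tokens = np.repeat(np.arange(n_attrs), remaining)
            rng.shuffle(tokens)
            # one token per remaining item first, then place the leftovers
            q[rest, tokens[: rest.size]] = 1
            capacity = np.ones(rest.size, dtype=np.int64) * (spec.max_attrs_per_item - 1)
            for k in tokens[rest.size :]:
                placed = False
                for _ in range(64):
                    j = rng.integers(rest.size)
                    if capacity[j] > 0 and q[rest[j], k] == 0:
                        q[rest[j], k] = 1
                        capacity[j] -= 1
                        placed = True
                        break
                if not placed:
                    eligible = np.flatnonzero((capacity > 0) & (q[rest, k] == 0))
                    if eligible.size:
                        j = int(rng.choice(eligible))
                        q[rest[j], k] = 1
                        capacity[j] -= 1
                    # else: token dropped; column sum falls short by one
        else:
            weights = _attribute_weights(spec)
            max_m = min(spec.max_attrs_per_item, n_attrs)
            # mostly single-attribute items, as in real MCQ banks
            m_probs = np.array([0.85, 0.10, 0.05][:max_m], dtype=float)
            m_probs /= m_probs.sum()
            for i in rest:
                m = rng.choice(np.arange(1, max_m + 1), p=m_probs)
                attrs = rng.choice(n_attrs, size=m, replace=False, p=weights)
                q[i, attrs] = 1
    names = spec.attribute_names
    return QMatrix(q, None, names)


def simulate_knowledge_states(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Latent N x K mastery states: explicit list, or independent
    Bernoulli(p_k) draws."""
    if spec.explicit_states is not None:
        return np.asarray(spec.explicit_states, dtype=np.uint8)
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    probs = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.mastery_prob, dtype=float)), (spec.n_attributes,)
    )
    return (rng.random((spec.n_examinees, spec.n_attributes)) < probs).astype(np.uint8)


def simulate_responses(
    q: QMatrix,
    states: np.ndarray,
    slip: float,
    guess: float,
    seed: int | np.random.Generator = 0,
    rule: str = "conjunctive",
) -> ResponseMatrix:
    """Noisy responses: P(correct) = 1 - slip where the ideal response is 1,
    guess where it is 0; independent across cells."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.asarray(states, dtype=np.uint8)
    table = conjunctive_table if rule == "conjunctive" else disjunctive_table
    ideal = table(states, q.entries)
    p_correct = np.where(ideal == 1, 1.0 - slip, guess)
    entries = (rng.random(ideal.shape) < p_correct).astype(np.int8)
    return ResponseMatrix(entries, None, q.item_ids)


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[QMatrix, ResponseMatrix, np.ndarray]:
    """Q-matrix, responses and the latent truth states, all from one seed."""
    rng = np.random.default_rng(spec.seed)
    q = simulate_qmatrix(spec, rng)
    states = simulate_knowledge_states(spec, rng)
    y = simulate_responses(q, states, spec.slip, spec.guess, rng, spec.generating_rule)
    return q, y, states
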