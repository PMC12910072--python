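"""Reliability and validity metrics for diagnostic classifications.

Covers the classical and CDA-specific quality checks: Cronbach's alpha for
internal consistency of the raw scores, split-half retest consistency of
the attribute classifications (how stably two independent half-tests
reproduce the same mastery calls), the mastery level (number of attributes
mastered), and its Pearson correlation with total test scores.

Retest consistency is operationalised as seeded stratified random
split-half re-classification agreement: items are split into two
half-tests, stratified by q-vector pattern so each attribute keeps coverage
in both halves; each half is classified independently and the attribute-
and pattern-level agreement between the two resulting state matrices is
averaged over replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .classify import ClassifierConfig, gnpc_classify, npc_classify, wgnpc_classify
from .matrices import QMatrix, ResponseMatrix

__all__ = [
    "ConsistencyReport",
    "cronbach_alpha",
    "retest_consistency",
    "mastery_level",
    "mastery_total_correlation",
]

_METHODS = {"npc": npc_classify, "gnpc": gnpc_classify, "wgnpc": wgnpc_classify}


def cronbach_alpha(y: ResponseMatrix) -> float:
    """Cronbach's alpha: (I / (I - 1)) * (1 - sum of item variances /
    total-score variance), with N-1 sample variances.

    Raises ``ValueError`` when the total-score variance is zero (alpha
    undefined) or the matrix is too small (needs N >= 2 and I >= 2).
    """
    entries = (y.entries if hasattr(y, "entries") else np.asarray(y)).astype(float)
    n, i = entries.shape
    if n < 2 or i < 2:
        raise ValueError("alpha needs at least 2 examinees and 2 items")
    total_var = entries.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    item_var = entries.var(axis=0, ddof=1).sum()
    return float(i / (i - 1) * (1.0 - item_var / total_var))


def mastery_level(alpha) -> int:
    """Number of attributes mastered: the sum of the knowledge state."""
    arr = np.asarray(getattr(alpha, "alpha", alpha))
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("knowledge state entries must be 0 or 1")
    return int(arr.sum())


def mastery_total_correlation(levels, total_scores) -> float:
    """Pearson correlation between mastery levels and total test scores."""
    levels = np.asarray(levels, dtype=float)
    total_scores = np.asarray(total_scores, dtype=float)
    if levels.shape != total_scores.shape or levels.ndim != 1:
        raise ValueError("levels and scores must be aligned 1-D vectors")
    if levels.size < 3:
        raise ValueError("correlation needs at least 3 examinees")
    if levels.std() == 0 or total_scores.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(levels, total_scores).statistic)


@dataclass(frozen=True)
class ConsistencyReport:
    """Split-half retest consistency of the attribute classifications."""

    attribute_consistency: float
    pattern_consistency: float
    design: str
    replicates: int
    seed: int
    method: str
    per_replicate_attribute: tuple[float, ...] = ()
    per_replicate_pattern: tuple[float, ...] = ()
    redraws: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _split_half(q_entries: np.ndarray, rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Deal items into two halves, stratified by q-vector pattern."""
    groups: dict[bytes, list[int]] = {}
    for i in range(q_entries.shape[0]):
        groups.setdefault(q_entries[i].tobytes(), []).append(i)
    half_a: list[int] = []
    half_b: list[int] = []
    for key in sorted(groups):
        idx = np.array(groups[key])
        rng.shuffle(idx)
        if rng.integers(2) == 0:
            half_a.extend(idx[0::2])
            half_b.extend(idx[1::2])
        else:
            half_a.extend(idx[1::2])
            half_b.extend(idx[0::2])
    return sorted(half_a), sorted(half_b)


def retest_consistency(
    y: ResponseMatrix,
    q: QMatrix,
    method: str = "wgnpc",
    replicates: int = 10,
    seed: int = 0,
    config: ClassifierConfig | None = None,
    max_redraws: int = 100,
) -> ConsistencyReport:
    """Stratified split-half re-classification agreement.

    For each replicate the items are split into two half-tests (stratified
    by q-vector pattern); splits leaving any attribute unmeasured in either
    half are redrawn, up to ``max_redraws`` per replicate.  Each half is
    classified independently with the requested method and the two state
    matrices are compared: attribute consistency is the fraction of
    agreeing attribute calls, pattern consistency the fraction of examinees
    with identical full states.  Values are averaged over replicates.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    if q.n_items < 2:
        raise ValueError("split-half consistency needs at least 2 items")
    if replicates < 1:
        raise ValueError("replicates must be positive")
    classify = _METHODS[method]
    rng = np.random.default_rng(seed)
    attr_cons: list[float] = []
    patt_cons: list[float] = []
    redraws = 0

    for _ in range(replicates):
        for attempt in range(max_redraws + 1):
            half_a, half_b = _split_half(q.entries, rng)
            ok = all(
                len(h) > 0
                and (q.entries[h] != 0).any(axis=0).all()
                for h in (half_a, half_b)
            )
            if ok:
                break
            redraws += 1
        else:
            raise RuntimeError(
                "could not draw a split covering every attribute in both halves; "
                "filter under-covered attributes first"
            )
        results = []
        for half in (half_a, half_b):
            sub_q = QMatrix(
                q.entries[half],
                tuple(q.item_ids[i] for i in half),
                q.attribute_names,
            )
            sub_y = ResponseMatrix(
                y.entries[:, half], y.examinee_ids, sub_q.item_ids
            )
            results.append(classify(sub_y, sub_q, config=config))
        a, b = results[0].states, results[1].states
        attr_cons.append(float((a == b).mean()))
        patt_cons.append(float((a == b).all(axis=1).mean()))

    return ConsistencyReport(
        attribute_consistency=float(np.mean(attr_cons)),
        pattern_consistency=float(np.mean(patt_cons)),
        design=(
            "stratified random split-half re-classification agreement "
            "(items dealt alternately within q-vector pattern groups)"
        ),
        replicates=replicates,
        seed=seed,
        method=method,
        per_replicate_attribute=tuple(attr_cons),
        per_replicate_pattern=tuple(patt_cons),
        redraws=redraws,
    )
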