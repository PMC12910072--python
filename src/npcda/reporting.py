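"""Mastery-profile summaries: per-attribute proportions, ranked examinee
profiles, and side-by-side profile comparison."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationResult

__all__ = [
    "attribute_mastery_proportion",
    "examinee_profile_table",
    "compare_profiles",
]


def attribute_mastery_proportion(result: ClassificationResult) -> pd.DataFrame:
    """Per-attribute mastery proportions over the classified examinees.

    Returns a frame with the count of examinees mastering each attribute
    and the proportion as a percentage rounded to two decimals (e.g. 40 of
    41 examinees -> 97.56).
    """
    n = result.states.shape[0]
    if n < 1:
        raise ValueError("need at least one examinee")
    counts = result.states.sum(axis=0).astype(np.int64)
    return pd.DataFrame(
        {
            "attribute": list(result.attribute_names),
            "mastered_count": counts,
            "proportion_pct": np.round(100.0 * counts / n, 2),
        }
    )


def examinee_profile_table(
    result: ClassificationResult,
    total_scores: Mapping[str, int] | Sequence[int] | np.ndarray,
) -> pd.DataFrame:
    """Examinee profiles sorted by total score descending (ties by id).

    ``total_scores`` is a mapping examinee id -> score, or a sequence
    aligned with the result's examinee order.
    """
    ids = list(result.examinee_ids)
    if isinstance(total_scores, Mapping):
        missing = [e for e in ids if e not in total_scores]
        if missing:
            raise ValueError(f"total scores missing for examinees: {missing[:5]}")
        extra = set(total_scores) - set(ids)
        if extra:
            raise ValueError(f"total scores given for unknown examinees: {sorted(extra)[:5]}")
        scores = [int(total_scores[e]) for e in ids]
    else:
        scores = [int(s) for s in total_scores]
        if len(scores) != len(ids):
            raise ValueError(f"expected {len(ids)} scores, got {len(scores)}")
    frame = pd.DataFrame(
        {
            "examinee_id": ids,
            "total_score": scores,
            "n_attributes_mastered": result.mastery_levels(),
            "state": result.state_strings(),
        }
    )
    frame = frame.sort_values(
        ["total_score", "examinee_id"], ascending=[False, True], kind="mergesort"
    )
    return frame.reset_index(drop=True)


def compare_profiles(
    result: ClassificationResult, examinee_ids: Sequence[str]
) -> pd.DataFrame:
    """Attributes on which a subset of examinees disagree.

    Attributes uniformly mastered or uniformly not mastered by the whole
    subset are excluded; the frame may be empty when the profiles are
    identical.  Columns are the subset members, rows the differing
    attributes.
    """
    ids = [str(e) for e in examinee_ids]
    if len(ids) < 2:
        raise ValueError("profile comparison needs at least 2 examinees")
    pos = {e: i for i, e in enumerate(result.examinee_ids)}
    missing = [e for e in ids if e not in pos]
    if missing:
        raise ValueError(f"unknown examinees: {missing[:5]}")
    sub = result.states[[pos[e] for e in ids]]
    differs = ~np.all(sub == sub[0], axis=0)
    frame = pd.DataFrame(
        sub[:, differs].T,
        index=pd.Index(
            [result.attribute_names[k] for k in np.flatnonzero(differs)], name="attribute"
        ),
        columns=ids,
    )
    return frame
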