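"""Scoring of raw multiple-choice answer records into a binary response matrix.

Examinee answers arrive as stored records — e.g. the JSON a language model
emitted when asked to answer single-best-answer MCQs — each naming an item
and a chosen option letter.  Scoring compares the chosen option with the
answer key: 1 point iff they match.  Records that are missing or could not
be parsed to a valid option score 0 (incorrect) and are logged; an answer
for an item that is not in the key at all is an error, since it signals
misaligned inputs rather than a wrong answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .matrices import ResponseMatrix

__all__ = [
    "AnswerRecord",
    "AnswerKey",
    "score_answers",
    "load_answer_records",
]

_OPTION_LETTERS = "ABCDEFGHIJ"


@dataclass(frozen=True)
class AnswerRecord:
    """One stored answer: the item, the chosen option, the verbatim payload.

    ``chosen_option`` is None when the stored response could not be parsed
    to an option letter; such records score 0.
    """

    item_id: str
    chosen_option: str | None
    raw_payload: str = ""


@dataclass(frozen=True)
class AnswerKey:
    """Item -> correct option mapping; exactly one correct option per item."""

    correct: Mapping[str, str]
    options_per_item: int = 5

    def __post_init__(self) -> None:
        if self.options_per_item < 2:
            raise ValueError("options_per_item must be at least 2")
        valid = set(_OPTION_LETTERS[: self.options_per_item])
        fixed = {}
        for item_id, opt in dict(self.correct).items():
            opt = str(opt).strip().upper()
            if opt not in valid:
                raise ValueError(
                    f"correct option {opt!r} for item {item_id!r} is not one of {sorted(valid)}"
                )
            fixed[str(item_id)] = opt
        object.__setattr__(self, "correct", fixed)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.correct)


def _normalise_option(value, n_options: int) -> str | None:
    if value is None:
        return None
    s = str(value).strip().upper()
    if len(s) > 1:
        # tolerate payloads like "A." or "(b)" but nothing ambiguous
        stripped = s.strip("().: ")
        if len(stripped) == 1:
            s = stripped
    if len(s) == 1 and s in _OPTION_LETTERS[:n_options]:
        return s
    return None


def score_answers(
    records: Mapping[str, Sequence[AnswerRecord]],
    key: AnswerKey,
) -> tuple[ResponseMatrix, list[str]]:
    """Score per-examinee answer records against the key.

    Parameters
    ----------
    records : mapping examinee id -> sequence of AnswerRecord
    key : AnswerKey

    Returns
    -------
    (ResponseMatrix, log)
        Responses with one column per key item (in key order) and one row
        per examinee (in mapping order); the log lists every record that
        scored 0 because it was missing or unparseable.

    Raises
    ------
    KeyError
        If a record names an item absent from the key.
    """
    item_ids = key.item_ids
    col = {iid: j for j, iid in enumerate(item_ids)}
    examinee_ids = tuple(str(e) for e in records)
    entries = np.zeros((len(examinee_ids), len(item_ids)), dtype=np.int8)
    log: list[str] = []

    for n, examinee in enumerate(examinee_ids):
        seen: set[str] = set()
        for rec in records[examinee]:
            if rec.item_id not in col:
                raise KeyError(
                    f"record for examinee {examinee!r} names unknown item {rec.item_id!r}"
                )
            seen.add(rec.item_id)
            chosen = _normalise_option(rec.chosen_option, key.options_per_item)
            if chosen is None:
                log.append(
                    f"examinee {examinee!r}, item {rec.item_id!r}: unparseable answer "
                    f"{rec.chosen_option!r}; scored 0"
                )
                continue
            if chosen == key.correct[rec.item_id]:
                entries[n, col[rec.item_id]] = 1
        for iid in item_ids:
            if iid not in seen:
                log.append(f"examinee {examinee!r}, item {iid!r}: no answer recorded; scored 0")
    return ResponseMatrix(entries, examinee_ids, item_ids), log


def load_answer_records(path) -> dict[str, list[AnswerRecord]]:
    """Load stored answer records from JSON.

    Accepts either a mapping ``{examinee_id: [{"item_id": ..., "answer": ...}, ...]}``
    or a bare array of record objects (treated as a single unnamed examinee).
    Records with a missing or null ``answer`` field are kept with
    ``chosen_option=None`` so that scoring can log them.
    """
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, list):
        raw = {"examinee1": raw}
    if not isinstance(raw, dict):
        raise ValueError("answer-record JSON must be an object or an array")
    out: dict[str, list[AnswerRecord]] = {}
    for examinee, items in raw.items():
        recs = []
        for obj in items:
            if "item_id" not in obj:
                raise ValueError(f"record without item_id for examinee {examinee!r}")
            answer = obj.get("answer")
            recs.append(
                AnswerRecord(
                    item_id=str(obj["item_id"]),
                    chosen_option=None if answer is None else str(answer),
                    raw_payload=json.dumps(obj, sort_keys=True),
                )
            )
        out[str(examinee)] = recs
    return out
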