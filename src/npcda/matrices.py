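"""Binary Q-matrix and response-matrix containers with CSV I/O.

A Q-matrix is the measurement design of a diagnostic test: an I x K binary
incidence matrix whose entry ``q_ik = 1`` says that item *i* measures
attribute *k* (a discrete skill or knowledge subdomain).  A response matrix
holds the scored answers of N examinees on the same I items, 1 for correct
and 0 for incorrect; each row is an examinee's observed response pattern
(ORP).

Items are identified by label at I/O boundaries.  Positional alignment
between a Q-matrix and a response matrix is established once, via
:func:`align`, after which all computation is positional.

Construction enforces only structural well-formedness (rectangular entries,
matching and unique labels, integer cells) so that :func:`validate_qmatrix`
can *report* content violations — non-binary cells, items measuring no
attribute — without ever mutating its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QMatrix",
    "ResponseMatrix",
    "ValidationReport",
    "FilterLog",
    "validate_qmatrix",
    "filter_low_coverage",
    "align",
    "read_qmatrix",
    "write_qmatrix",
    "read_responses",
    "write_responses",
]


def _coerce_int_matrix(values, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{what} must have at least one row and one column")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.issubdtype(arr.dtype, np.floating):
            raise ValueError(f"{what} entries must be numeric")
        rounded = np.rint(arr)
        if not np.array_equal(rounded, arr):
            raise ValueError(f"{what} entries must be integer-valued")
        arr = rounded
    return arr.astype(np.int8)


def _coerce_labels(labels, n: int, what: str, default_prefix: str) -> tuple[str, ...]:
    if labels is None:
        return tuple(f"{default_prefix}{i + 1}" for i in range(n))
    out = tuple(str(x) for x in labels)
    if len(out) != n:
        raise ValueError(f"expected {n} {what}, got {len(out)}")
    if len(set(out)) != len(out):
        raise ValueError(f"{what} must be unique")
    return out


@dataclass(frozen=True)
class QMatrix:
    """Item-by-attribute binary incidence matrix.

    Attributes
    ----------
    entries : (I, K) int8 array
        ``entries[i, k] = 1`` iff item *i* measures attribute *k*.
    item_ids : tuple of str
        Unique item labels, one per row.
    attribute_names : tuple of str
        Unique attribute labels, one per column.
    """

    entries: np.ndarray
    item_ids: tuple[str, ...] = None  # type: ignore[assignment]
    attribute_names: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = _coerce_int_matrix(self.entries, "Q-matrix")
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)
        object.__setattr__(
            self, "item_ids", _coerce_labels(self.item_ids, arr.shape[0], "item ids", "item")
        )
        object.__setattr__(
            self,
            "attribute_names",
            _coerce_labels(self.attribute_names, arr.shape[1], "attribute names", "A"),
        )

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=pd.Index(self.item_ids, name="item_id"),
            columns=list(self.attribute_names),
        )


@dataclass(frozen=True)
class ResponseMatrix:
    """Examinee-by-item binary observed responses (rows are ORPs)."""

    entries: np.ndarray
    examinee_ids: tuple[str, ...] = None  # type: ignore[assignment]
    item_ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = _coerce_int_matrix(self.entries, "response matrix")
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValueError(
                f"non-binary response value at row {bad[0]}, column {bad[1]}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)
        object.__setattr__(
            self,
            "examinee_ids",
            _coerce_labels(self.examinee_ids, arr.shape[0], "examinee ids", "examinee"),
        )
        object.__setattr__(
            self, "item_ids", _coerce_labels(self.item_ids, arr.shape[1], "item ids", "item")
        )

    @property
    def n_examinees(self) -> int:
        return self.entries.shape[0]

    @property
    def n_items(self) -> int:
        return self.entries.shape[1]

    def total_scores(self) -> np.ndarray:
        """Number of items answered correctly per examinee (one point each)."""
        return self.entries.sum(axis=1).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            index=pd.Index(self.examinee_ids, name="examinee_id"),
            columns=list(self.item_ids),
        )


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...] = ()


def validate_qmatrix(q: QMatrix) -> ValidationReport:
    """Check the Q-matrix content invariants, reporting every violation.

    The invariants: every cell is 0 or 1, and no item has an all-zero
    q-vector (every item must measure at least one attribute).  The input is
    never mutated; a report is returned even when violations are found.
    """
    violations: list[str] = []
    entries = q.entries
    bad = ~np.isin(entries, (0, 1))
    for i, k in np.argwhere(bad):
        violations.append(
            f"non-binary value {int(entries[i, k])} at item {q.item_ids[i]!r}, "
            f"attribute {q.attribute_names[k]!r}"
        )
    # all-zero q-vector check only meaningful over binary-valid rows
    row_zero = (entries == 0).all(axis=1)
    for i in np.flatnonzero(row_zero):
        violations.append(f"all-zero q-vector at item {q.item_ids[i]!r}")
    return ValidationReport(ok=not violations, violations=tuple(violations))


@dataclass(frozen=True)
class FilterLog:
    """Record of what the attribute-coverage filter removed."""

    min_count: int
    removed_attributes: tuple[str, ...]
    removed_items: tuple[str, ...]


def filter_low_coverage(
    q: QMatrix,
    y: ResponseMatrix | None = None,
    min_count: int = 3,
) -> tuple[QMatrix, ResponseMatrix | None, FilterLog]:
    """Drop attributes measured by fewer than ``min_count`` items.

    Under-covered attribute columns are removed first; items whose q-vector
    becomes all-zero (they measured only removed attributes) are then
    dropped from both the Q-matrix and the response matrix.  Because every
    dropped item contributed nothing to the surviving columns, the filter is
    idempotent.

    Raises
    ------
    ValueError
        If ``min_count`` is negative, or if the filter would remove every
        attribute.
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    if y is not None and tuple(y.item_ids) != tuple(q.item_ids):
        raise ValueError("Q-matrix and responses are not item-aligned; call align() first")

    counts = q.entries.sum(axis=0)
    keep_attr = counts >= min_count
    if not keep_attr.any():
        raise ValueError(
            f"every attribute removed: all column sums < min_count={min_count}"
        )
    sub = q.entries[:, keep_attr]
    keep_item = sub.sum(axis=1) > 0

    removed_attrs = tuple(
        name for name, keep in zip(q.attribute_names, keep_attr) if not keep
    )
    removed_items = tuple(
        iid for iid, keep in zip(q.item_ids, keep_item) if not keep
    )
    q_out = QMatrix(
        sub[keep_item],
        tuple(iid for iid, keep in zip(q.item_ids, keep_item) if keep),
        tuple(name for name, keep in zip(q.attribute_names, keep_attr) if keep),
    )
    y_out: ResponseMatrix | None = None
    if y is not None:
        y_out = ResponseMatrix(
            y.entries[:, keep_item], y.examinee_ids, q_out.item_ids
        )
    log = FilterLog(min_count, removed_attrs, removed_items)
    return q_out, y_out, log


def align(q: QMatrix, y: ResponseMatrix) -> ResponseMatrix:
    """Reorder response columns to match the Q-matrix item order by label."""
    if tuple(y.item_ids) == tuple(q.item_ids):
        return y
    pos = {iid: j for j, iid in enumerate(y.item_ids)}
    missing = [iid for iid in q.item_ids if iid not in pos]
    if missing:
        raise ValueError(f"responses lack items present in the Q-matrix: {missing[:5]}")
    extra = set(y.item_ids) - set(q.item_ids)
    if extra:
        raise ValueError(
            f"responses contain items absent from the Q-matrix: {sorted(extra)[:5]}"
        )
    order = [pos[iid] for iid in q.item_ids]
    return ResponseMatrix(y.entries[:, order], y.examinee_ids, q.item_ids)


# ---------------------------------------------------------------------------
# CSV I/O.  First column = row id, header row = column labels, cells in {0,1}.
# ---------------------------------------------------------------------------


def _read_binary_frame(path, row_kind: str, col_kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no rows")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary value {cell!r} at {row_kind} "
                    f"{df.index[i]!r}, {col_kind} {df.columns[j]!r}"
                )
            values[i, j] = int(cell)
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def read_qmatrix(path) -> QMatrix:
    df = _read_binary_frame(path, "item", "attribute")
    return QMatrix(df.to_numpy(), tuple(df.index), tuple(df.columns))


def write_qmatrix(q: QMatrix, path) -> None:
    q.to_frame().to_csv(path)


def read_responses(path) -> ResponseMatrix:
    df = _read_binary_frame(path, "examinee", "item")
    return ResponseMatrix(df.to_numpy(), tuple(df.index), tuple(df.columns))


def write_responses(y: ResponseMatrix, path) -> None:
    y.to_frame().to_csv(path)
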