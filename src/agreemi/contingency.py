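"""Contingency-table data model, section maps and score dichotomization.

A :class:`ContingencyTable` cross-tabulates paired categorical outcomes from
two instruments (rows = instrument A, columns = instrument B).  A
:class:`SectionMap` designates which cells count as evidence of agreement
(weight 1), disagreement (weight 0) or partial agreement (fractional weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "SectionMap",
    "ScoreVector",
    "TableValidationError",
    "build_table",
    "joint_and_marginals",
    "default_section_map",
    "dichotomize",
]


class TableValidationError(ValueError):
    """Raised when input counts, labels or weights violate table invariants."""


def _as_labels(labels: Sequence[str] | None, n: int, axis: str) -> tuple[str, ...]:
    # default labels are axis-independent ("cat1", ...) so an unlabeled square
    # table still qualifies for kappa and the diagonal section map
    if labels is None:
        return tuple(f"cat{i + 1}" for i in range(n))
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise TableValidationError(
            f"{len(labels)} labels supplied for {n} {axis} categories"
        )
    if len(set(labels)) != len(labels):
        raise TableValidationError(f"duplicate labels: {labels}")
    return labels


@dataclass(frozen=True)
class ContingencyTable:
    """Validated m x q matrix of non-negative counts with category labels.

    Counts may be non-negative reals (pooled or weighted tables); significance
    tests warn when the total is non-integer.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    col_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise TableValidationError("counts must be a 2-D rectangular matrix")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise TableValidationError("table must be at least 2x2")
        if not np.all(np.isfinite(counts)):
            raise TableValidationError("counts must be finite")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise TableValidationError(f"negative count at cell ({i}, {j})")
        if counts.sum() == 0:
            raise TableValidationError("table is all zero")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(
            self, "row_labels", _as_labels(self.row_labels, counts.shape[0], "row")
        )
        object.__setattr__(
            self, "col_labels", _as_labels(self.col_labels, counts.shape[1], "col")
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n(self) -> float:
        """Total count; returned as int when the sum is integral."""
        total = float(self.counts.sum())
        return int(total) if total.is_integer() else total

    @property
    def joint(self) -> np.ndarray:
        """Joint probability matrix P(x_ij) = x_ij / n."""
        return self.counts / self.counts.sum()

    @property
    def row_marginals(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy(), self.col_labels, self.row_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ContingencyTable":
        return cls(frame.to_numpy(dtype=float), tuple(map(str, frame.index)),
                   tuple(map(str, frame.columns)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ContingencyTable({self.shape[0]}x{self.shape[1]}, n={self.n})"


@dataclass(frozen=True)
class SectionMap:
    """Per-cell agreement weights in [0, 1].

    Weight 1 marks a pure agreement section, 0 a pure disagreement section;
    fractional weights express partial agreement.  Each category of each
    instrument should contain at least one agreement and one disagreement
    section; violations are reported as a warning because externally supplied
    weighted maps may legitimately break the rule.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise TableValidationError("weights must be a 2-D matrix")
        if not np.all(np.isfinite(w)) or np.any(w < 0) or np.any(w > 1):
            raise TableValidationError("weights must lie in [0, 1]")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        rows_bad = np.any(~np.any(w > 0, axis=1)) or np.any(~np.any(w < 1, axis=1))
        cols_bad = np.any(~np.any(w > 0, axis=0)) or np.any(~np.any(w < 1, axis=0))
        if rows_bad or cols_bad:
            warnings.warn(
                "section map leaves some category without both an agreement "
                "(weight > 0) and a disagreement (weight < 1) section; the "
                "recommended design gives every category at least one of each",
                UserWarning,
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def transpose(self) -> "SectionMap":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return SectionMap(self.weights.T.copy())


@dataclass(frozen=True)
class ScoreVector:
    """Numeric instrument scores, e.g. delirium-severity ratings on a 0-39 scale."""

    values: np.ndarray
    scale_max: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise TableValidationError("scores must be a non-empty 1-D vector")
        if not np.all(np.isfinite(v)):
            raise TableValidationError("scores must be finite")
        if self.scale_max is not None and (np.any(v < 0) or np.any(v > self.scale_max)):
            raise TableValidationError(f"scores must lie in [0, {self.scale_max}]")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


def build_table(
    counts,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Validate a count matrix and return a :class:`ContingencyTable`.

    Raises :class:`TableValidationError` for ragged, negative, all-zero or
    sub-2x2 input.
    """
    arr = np.asarray(counts, dtype=object)
    if arr.ndim != 2:
        raise TableValidationError("counts must be a rectangular (non-ragged) matrix")
    return ContingencyTable(np.asarray(counts, dtype=float), row_labels, col_labels)


def joint_and_marginals(
    table: ContingencyTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (joint probability matrix, row marginals, column marginals)."""
    return table.joint, table.row_marginals, table.col_marginals


def default_section_map(table: ContingencyTable) -> SectionMap:
    """Diagonal section map: weight 1 on matching categories, 0 elsewhere.

    Only defined for square tables whose row and column label sequences are
    identical (exact, order-sensitive string match); anything else needs an
    explicit :class:`SectionMap`.
    """
    m, q = table.shape
    if m != q or table.row_labels != table.col_labels:
        raise TableValidationError(
            "default diagonal section map requires a square table with "
            "identical row/column categories in the same order; supply an "
            "explicit SectionMap for this table"
        )
    return SectionMap(np.eye(m))


def dichotomize(
    scores: ScoreVector | Sequence[float],
    cutoff: float,
    rule: str = "ge",
) -> list[str]:
    """Convert numeric scores to positive/negative via a cut-off.

    rule="ge" (default): score >= cutoff -> "positive"; rule="gt": strict.
    """
    if not isinstance(scores, ScoreVector):
        scores = ScoreVector(np.asarray(scores, dtype=float))
    if rule not in ("ge", "gt"):
        raise ValueError("rule must be 'ge' or 'gt'")
    op = np.greater_equal if rule == "ge" else np.greater
    return ["positive" if flag else "negative" for flag in op(scores.values, cutoff)]
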