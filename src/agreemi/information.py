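"""Mutual information, its local decomposition and the chi-square significance test.

All information quantities are in bits (log base 2).  Mutual information

    I(A; B) = sum_ij P(x_ij) log2[ P(x_ij) / (P(x_i.) P(x_.j)) ]

is the sum of per-cell *local* mutual information terms; splitting that sum
over agreement vs. disagreement sections gives I_agreement and
I_disagreement.  The significance of I is assessed through the equivalent
likelihood-ratio (G) statistic 2 n ln2 * I, asymptotically chi-square with
(m-1)(q-1) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contingency import ContingencyTable, SectionMap, TableValidationError

__all__ = [
    "LocalMIMatrix",
    "SignificanceResult",
    "DegenerateInputError",
    "local_mi_matrix",
    "mutual_information",
    "sectioned_information",
    "g_statistic",
    "mi_p_value",
    "mi_significance_threshold",
    "marginal_entropies",
]

LN2 = float(np.log(2.0))


class DegenerateInputError(ValueError):
    """A positive probability cell sits on a zero marginal (p*log2(p/0) = inf).

    Unreachable from count tables (a zero marginal forces zero cells), so it
    can only arise from externally constructed probability matrices; flagged
    rather than silently propagated as infinity.
    """


@dataclass(frozen=True)
class LocalMIMatrix:
    """Per-cell contributions (bits) to the mutual information of a table."""

    contributions: np.ndarray

    @property
    def total(self) -> float:
        return float(self.contributions.sum())


@dataclass(frozen=True)
class SignificanceResult:
    """A test statistic with degrees of freedom and upper-tail p-value."""

    statistic: float
    dof: int | None
    p_value: float | None
    method: str

    def significant(self, alpha: float) -> bool:
        if self.p_value is None:
            raise ValueError(f"{self.method}: p-value undefined")
        return self.p_value < alpha


def _local_mi_from_joint(
    joint: np.ndarray,
    row_marginals: np.ndarray | None = None,
    col_marginals: np.ndarray | None = None,
) -> np.ndarray:
    """Local MI (bits) per cell; convention 0*log2(0/p) = 0.

    Marginals default to the joint's own sums, in which case a positive cell
    always has positive marginals and the p*log2(p/0) = inf branch cannot
    trigger.  Explicitly supplied (externally constructed) marginals may be
    inconsistent with the joint; that degenerate case raises
    :class:`DegenerateInputError` instead of silently propagating infinity.
    """
    joint = np.asarray(joint, dtype=float)
    rows = (joint.sum(axis=1) if row_marginals is None
            else np.asarray(row_marginals, dtype=float)).reshape(-1, 1)
    cols = (joint.sum(axis=0) if col_marginals is None
            else np.asarray(col_marginals, dtype=float)).reshape(1, -1)
    expected = rows * cols
    out = np.zeros_like(joint)
    pos = joint > 0
    if np.any(pos & (expected == 0)):
        raise DegenerateInputError(
            "positive probability cell with a zero marginal: local mutual "
            "information is infinite for this degenerate input"
        )
    out[pos] = joint[pos] * np.log2(joint[pos] / expected[pos])
    return out


def local_mi_matrix(table: ContingencyTable) -> LocalMIMatrix:
    """Per-cell local mutual information P(x_ij) log2[P(x_ij)/(P(x_i.)P(x_.j))]."""
    return LocalMIMatrix(_local_mi_from_joint(table.joint))


def mutual_information(table: ContingencyTable) -> float:
    """Mutual information (bits) between the two instruments' outcomes."""
    # clip the tiny negative float noise possible near exact independence
    return max(local_mi_matrix(table).total, 0.0)


def sectioned_information(
    table: ContingencyTable, sections: SectionMap
) -> tuple[float, float]:
    """Split MI into (I_agreement, I_disagreement) via the section weights.

    I_agreement = sum w_ij L_ij and I_disagreement = sum (1 - w_ij) L_ij,
    which for 0/1 weights reduces to plain sums over the agreement and
    disagreement cell sets; the two components always add up to the table's
    mutual information.
    """
    if sections.shape != table.shape:
        raise TableValidationError(
            f"section map shape {sections.shape} != table shape {table.shape}"
        )
    local = local_mi_matrix(table).contributions
    i_agr = float((sections.weights * local).sum())
    i_dis = float(((1.0 - sections.weights) * local).sum())
    return i_agr, i_dis


def _effective_dof(table: ContingencyTable) -> int:
    """(m-1)(q-1) after dropping zero-marginal rows/columns.

    Empty categories carry no information and would deflate the statistic's
    reference distribution.
    """
    m = int(np.sum(table.counts.sum(axis=1) > 0))
    q = int(np.sum(table.counts.sum(axis=0) > 0))
    if m < table.shape[0] or q < table.shape[1]:
        warnings.warn(
            "zero-marginal rows/columns dropped when computing degrees of freedom",
            UserWarning,
            stacklevel=3,
        )
    return max((m - 1) * (q - 1), 1)


def g_statistic(table: ContingencyTable) -> SignificanceResult:
    """Likelihood-ratio statistic 2 n ln2 * I(bits), chi-square scale."""
    n = float(table.counts.sum())
    if not float(n).is_integer():
        warnings.warn(
            "non-integer total count: the chi-square approximation assumes "
            "multinomial sampling of whole observations",
            UserWarning,
            stacklevel=2,
        )
    stat = 2.0 * n * LN2 * mutual_information(table)
    return SignificanceResult(stat, None, None, "G (likelihood-ratio) statistic")


def mi_p_value(table: ContingencyTable) -> SignificanceResult:
    """Chi-square test of the mutual information: G ~ chi2((m-1)(q-1))."""
    stat = g_statistic(table).statistic
    dof = _effective_dof(table)
    p = float(stats.chi2.sf(stat, dof))
    return SignificanceResult(stat, dof, p, "mutual-information chi-square test")


def mi_significance_threshold(n: float, dof: int = 1, alpha: float = 0.05) -> float:
    """Smallest MI (bits) significant at ``alpha`` for sample size ``n``.

    Inverts the G conversion at the chi-square critical value:
    chi2_crit(1-alpha, dof) / (2 n ln2).  Scales as 1/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, dof)) / (2.0 * n * LN2)


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def marginal_entropies(table: ContingencyTable) -> tuple[float, float, float]:
    """(row entropy, column entropy, joint entropy) in bits, 0*log0 = 0.

    Supports the identity I = H(row) + H(col) - H(joint).
    """
    return (
        _entropy_bits(table.row_marginals),
        _entropy_bits(table.col_marginals),
        _entropy_bits(table.joint),
    )
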