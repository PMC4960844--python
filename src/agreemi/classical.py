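"""Classical comparator measures: raw agreement, Cohen's kappa, odds ratio.

These are the measures the mutual-information procedure is compared against.
Kappa is chance-corrected agreement for two raters on the same categories,
kappa = (P(a) - P(e)) / (1 - P(e)); the odds ratio x11*x22 / (x12*x21)
measures association on a 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contingency import ContingencyTable, SectionMap, TableValidationError
from .information import SignificanceResult

__all__ = [
    "MeasureResult",
    "raw_agreement",
    "cohens_kappa",
    "kappa_significance",
    "odds_ratio",
    "odds_ratio_significance",
    "pearson_correlation",
]


@dataclass(frozen=True)
class MeasureResult:
    """A scalar agreement/association measure with optional significance."""

    value: float  # may be +inf (odds ratio) or nan (undefined)
    method: str
    significance: SignificanceResult | None = None
    note: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def raw_agreement(table: ContingencyTable, sections: SectionMap) -> float:
    """Weighted proportion of observations in agreement sections: sum w_ij x_ij / n."""
    if sections.shape != table.shape:
        raise TableValidationError("section map shape does not match table")
    return float((sections.weights * table.counts).sum() / table.counts.sum())


def _require_square(table: ContingencyTable, what: str) -> None:
    m, q = table.shape
    if m != q or table.row_labels != table.col_labels:
        raise TableValidationError(
            f"{what} is only defined for two raters using the same categories "
            "(square table, identical row/column labels)"
        )


def cohens_kappa(table: ContingencyTable) -> MeasureResult:
    """Cohen's kappa (P(a) - P(e)) / (1 - P(e)) with a null-hypothesis z test.

    P(a) is the diagonal probability mass, P(e) the chance agreement
    sum_i P(x_i.) P(x_.i).  Undefined when P(e) = 1 (all mass in a single
    category on both axes).
    """
    _require_square(table, "Cohen's kappa")
    joint = table.joint
    p_a = float(np.trace(joint))
    p_e = float(np.dot(table.row_marginals, table.col_marginals))
    if p_e >= 1.0 - 1e-15:
        return MeasureResult(
            float("nan"),
            "Cohen's kappa",
            note="undefined: chance agreement P(e) = 1 (all mass in one category)",
        )
    kappa = (p_a - p_e) / (1.0 - p_e)
    return MeasureResult(kappa, "Cohen's kappa", significance=kappa_significance(table))


def kappa_significance(table: ContingencyTable, alpha: float = 0.05) -> SignificanceResult:
    """Large-sample z test of kappa against 0 using the null standard error.

    SE0 = sqrt( (P(e) + P(e)^2 - sum_i p_i. p_.i (p_i. + p_.i)) / n ) / (1 - P(e))
    (Fleiss-Cohen-Everitt form computed from the marginals alone).
    """
    _require_square(table, "kappa significance")
    r, c = table.row_marginals, table.col_marginals
    p_e = float(np.dot(r, c))
    n = float(table.counts.sum())
    if p_e >= 1.0 - 1e-15:
        return SignificanceResult(float("nan"), None, None, "kappa z test (undefined)")
    var0 = (p_e + p_e**2 - float(np.sum(r * c * (r + c)))) / (n * (1.0 - p_e) ** 2)
    if var0 <= 0:
        return SignificanceResult(float("nan"), None, None, "kappa z test (undefined)")
    joint = table.joint
    kappa = (float(np.trace(joint)) - p_e) / (1.0 - p_e)
    z = kappa / math.sqrt(var0)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SignificanceResult(z, None, p, "kappa z test (null SE)")


def odds_ratio(table: ContingencyTable, haldane: bool = False) -> MeasureResult:
    """Odds ratio x11*x22 / (x12*x21) of a 2x2 table.

    A zero in the denominator with a positive numerator gives +infinity
    (reported as such so published infinite ORs reproduce); zeros in both
    give an undefined result.  ``haldane=True`` adds 0.5 to every cell
    (Haldane-Anscombe correction), making the ratio finite for every table;
    it is off by default.
    """
    if table.shape != (2, 2):
        raise TableValidationError("odds ratio is only defined for 2x2 tables")
    x = table.counts + (0.5 if haldane else 0.0)
    num = x[0, 0] * x[1, 1]
    den = x[0, 1] * x[1, 0]
    method = "odds ratio" + (" (Haldane-Anscombe corrected)" if haldane else "")
    if den == 0 and num == 0:
        return MeasureResult(float("nan"), method, note="undefined: 0/0")
    if den == 0:
        return MeasureResult(
            float("inf"), method, note="infinite since one of the cells contains 0"
        )
    sig = odds_ratio_significance(table, haldane=haldane) if np.all(x > 0) else None
    return MeasureResult(float(num / den), method, significance=sig)


def odds_ratio_significance(
    table: ContingencyTable, alpha: float = 0.05, haldane: bool = False
) -> SignificanceResult:
    """Wald z test of ln(OR) = 0 with SE = sqrt(sum of reciprocal cells)."""
    if table.shape != (2, 2):
        raise TableValidationError("odds ratio is only defined for 2x2 tables")
    x = table.counts + (0.5 if haldane else 0.0)
    if np.any(x == 0):
        return SignificanceResult(
            float("nan"), None, None, "log-OR Wald test (undefined: zero cell)"
        )
    log_or = math.log(x[0, 0] * x[1, 1] / (x[0, 1] * x[1, 0]))
    se = math.sqrt(float((1.0 / x).sum()))
    z = log_or / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SignificanceResult(z, None, p, "log-OR Wald test")


def log_or_confidence_interval(
    table: ContingencyTable, alpha: float = 0.05, haldane: bool = False
) -> tuple[float, float]:
    """(1 - alpha) Wald confidence interval for ln(OR)."""
    if table.shape != (2, 2):
        raise TableValidationError("odds ratio is only defined for 2x2 tables")
    x = table.counts + (0.5 if haldane else 0.0)
    if np.any(x == 0):
        raise TableValidationError("CI undefined with a zero cell (enable haldane)")
    log_or = math.log(x[0, 0] * x[1, 1] / (x[0, 1] * x[1, 0]))
    se = math.sqrt(float((1.0 / x).sum()))
    zq = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return log_or - zq * se, log_or + zq * se


def pearson_correlation(xs, ys) -> float:
    """Pearson r between two equal-length series; nan if variance is zero."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("need two equal-length series with at least 3 points")
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise ValueError("series must be finite")
    if np.std(xs) == 0 or np.std(ys) == 0:
        return float("nan")
    return float(stats.pearsonr(xs, ys).statistic)
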