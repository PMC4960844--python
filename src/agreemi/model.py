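"""The agreement procedure as a model/results pair.

:class:`InstrumentAgreement` wraps a contingency table plus its section map;
``fit()`` runs the four-step procedure — measure mutual information, test its
significance against chi-square, split it over agreement vs. disagreement
sections, and classify — and returns :class:`AgreementResults` carrying every
measure, the verdict, and a ``summary()`` table.

Verdict rule: if the MI chi-square p-value >= alpha the comparison is
*inconclusive* (true independence or insufficient data — the procedure cannot
distinguish the two); otherwise the verdict is *agreement* when
I_agreement > I_disagreement and *disagreement* when the reverse holds.  An
exact tie with significant MI is reported as inconclusive with a direction-tie
note.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .classical import (
    MeasureResult,
    cohens_kappa,
    odds_ratio,
    raw_agreement,
)
from .contingency import (
    ContingencyTable,
    ScoreVector,
    SectionMap,
    build_table,
    default_section_map,
    dichotomize,
)
from .information import (
    SignificanceResult,
    mi_p_value,
    mutual_information,
    sectioned_information,
)

__all__ = ["InstrumentAgreement", "AgreementResults", "classify", "full_report"]

# presentation-layer p-value bands mirroring common reporting conventions
_P_BANDS = ((0.001, "highly significant (p < 0.001)"),
            (0.01, "significant (p < 0.01)"),
            (0.05, "significant (p < 0.05)"),
            (0.1, "marginally significant (p < 0.1)"))


def _p_band(p: float) -> str:
    for cut, label in _P_BANDS:
        if p < cut:
            return label
    return "not significant (p >= 0.1)"


class InstrumentAgreement:
    """Agreement model for paired outcomes of two survey instruments.

    Parameters
    ----------
    table:
        Contingency table of paired counts (rows = instrument A categories,
        columns = instrument B).
    sections:
        Agreement-weight map; defaults to the diagonal map (weight 1 on
        matching categories) when the table is square with identical labels.
    alpha:
        Significance level for the MI chi-square test (default 0.05).
    haldane:
        Apply the +0.5 Haldane-Anscombe correction to the odds ratio.
    """

    def __init__(
        self,
        table: ContingencyTable,
        sections: SectionMap | None = None,
        alpha: float = 0.05,
        haldane: bool = False,
    ) -> None:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.table = table
        self.sections = sections if sections is not None else default_section_map(table)
        self.alpha = float(alpha)
        self.haldane = bool(haldane)

    @classmethod
    def from_counts(
        cls,
        counts,
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
        **kwargs,
    ) -> "InstrumentAgreement":
        return cls(build_table(counts, row_labels, col_labels), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "InstrumentAgreement":
        return cls(ContingencyTable.from_frame(frame), **kwargs)

    @classmethod
    def from_observations(
        cls, ratings_a: Sequence[str], ratings_b: Sequence[str], **kwargs
    ) -> "InstrumentAgreement":
        """Cross-tabulate two paired categorical rating sequences."""
        ct = pd.crosstab(pd.Series(ratings_a), pd.Series(ratings_b))
        labels = sorted(set(ct.index) | set(ct.columns))
        ct = ct.reindex(index=labels, columns=labels, fill_value=0)
        return cls.from_dataframe(ct, **kwargs)

    @classmethod
    def from_scores(
        cls,
        scores_a: ScoreVector | Sequence[float],
        scores_b: ScoreVector | Sequence[float],
        cutoff_a: float,
        cutoff_b: float | None = None,
        rule: str = "ge",
        **kwargs,
    ) -> "InstrumentAgreement":
        """Dichotomize two paired numeric score vectors, then cross-tabulate.

        Severity scales (e.g. a 0-39 delirium rating with the conventional
        cut-off of 16 or 17) become positive/negative outcomes via
        ``score >= cutoff`` (or ``>`` with rule="gt").
        """
        cutoff_b = cutoff_a if cutoff_b is None else cutoff_b
        a = dichotomize(scores_a, cutoff_a, rule)
        b = dichotomize(scores_b, cutoff_b, rule)
        if len(a) != len(b):
            raise ValueError("score vectors must be paired (equal length)")
        ct = pd.crosstab(pd.Series(a), pd.Series(b))
        labels = ["positive", "negative"]
        ct = ct.reindex(index=labels, columns=labels, fill_value=0)
        return cls.from_dataframe(ct, **kwargs)

    def fit(self) -> "AgreementResults":
        """Run the procedure and return the populated results object."""
        table, sections = self.table, self.sections
        mi = mutual_information(table)
        i_agr, i_dis = sectioned_information(table, sections)
        significance = mi_p_value(table)

        if significance.p_value >= self.alpha:
            verdict, note = "inconclusive", (
                "mutual information not significant: either true independence "
                "or insufficient data"
            )
        elif i_agr > i_dis:
            verdict, note = "agreement", None
        elif i_dis > i_agr:
            verdict, note = "disagreement", None
        else:
            verdict, note = "inconclusive", (
                "direction tie: significant mutual information but "
                "I_agreement == I_disagreement exactly"
            )

        kappa: MeasureResult | None
        try:
            kappa = cohens_kappa(table)
        except Exception:
            kappa = None
        odds: MeasureResult | None
        if table.shape == (2, 2):
            odds = odds_ratio(table, haldane=self.haldane)
        else:
            odds = None

        return AgreementResults(
            model=self,
            mutual_information=mi,
            i_agreement=i_agr,
            i_disagreement=i_dis,
            significance=significance,
            verdict=verdict,
            verdict_note=note,
            kappa=kappa,
            odds=odds,
            raw_agreement=raw_agreement(table, sections),
        )


@dataclass(frozen=True)
class AgreementResults:
    """Fitted agreement measures, significance and verdict for one table."""

    model: InstrumentAgreement
    mutual_information: float
    i_agreement: float
    i_disagreement: float
    significance: SignificanceResult
    verdict: str
    verdict_note: str | None
    kappa: MeasureResult | None
    odds: MeasureResult | None
    raw_agreement: float
    _extras: dict = field(default_factory=dict, repr=False)

    @property
    def alpha(self) -> float:
        return self.model.alpha

    def to_dict(self) -> dict:
        """Full-precision, JSON-serialisable report."""
        sig = self.significance

        def _num(x):
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return None
            if isinstance(x, float) and math.isinf(x):
                return "Infinity"
            return x

        table = self.model.table
        out = {
            "table": {
                "counts": table.counts.tolist(),
                "row_labels": list(table.row_labels),
                "col_labels": list(table.col_labels),
                "n": table.n,
            },
            "section_weights": self.model.sections.weights.tolist(),
            "alpha": self.alpha,
            "mutual_information": self.mutual_information,
            "i_agreement": self.i_agreement,
            "i_disagreement": self.i_disagreement,
            "chi_square": {
                "statistic": sig.statistic,
                "dof": sig.dof,
                "p_value": sig.p_value,
                "band": _p_band(sig.p_value),
            },
            "verdict": self.verdict,
            "verdict_note": self.verdict_note,
            "raw_agreement": self.raw_agreement,
            "kappa": None,
            "odds_ratio": None,
        }
        if self.kappa is not None:
            out["kappa"] = {
                "value": _num(self.kappa.value),
                "p_value": (
                    self.kappa.significance.p_value if self.kappa.significance else None
                ),
                "note": self.kappa.note,
            }
        else:
            out["kappa"] = {"value": None,
                            "note": "kappa requires a square table with matching "
                                    "categories (two raters, same scale)"}
        if self.odds is not None:
            out["odds_ratio"] = {
                "value": _num(self.odds.value),
                "p_value": (
                    self.odds.significance.p_value if self.odds.significance else None
                ),
                "note": self.odds.note,
            }
        else:
            out["odds_ratio"] = {"value": None,
                                 "note": "odds ratio is only defined for 2x2 tables"}
        return out

    def to_json(self, indent: int = 2) -> str:
        """Deterministic JSON: identical inputs and config give identical bytes."""
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary(self) -> str:
        """Plain-text report; numbers rendered to 3 decimals, verdict computed
        on full precision."""
        t = self.model.table
        sig = self.significance

        def f3(x):
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return "undefined"
            if isinstance(x, float) and math.isinf(x):
                return "inf"
            return f"{x:.3f}"

        frame = t.to_frame()
        if (frame.to_numpy() % 1 == 0).all():
            frame = frame.astype(int)
        lines = [
            "Instrument agreement analysis",
            "=============================",
            f"table: {t.shape[0]}x{t.shape[1]}, n = {t.n}",
            "",
            frame.to_string(),
            "",
            f"mutual information     {f3(self.mutual_information)} bits",
            f"  I_agreement          {f3(self.i_agreement)} bits",
            f"  I_disagreement       {f3(self.i_disagreement)} bits",
            f"chi-square statistic   {f3(sig.statistic)}  (dof = {sig.dof})",
            f"p-value                {sig.p_value:.3g}  [{_p_band(sig.p_value)}]",
            f"raw agreement          {f3(self.raw_agreement)}",
        ]
        if self.kappa is not None:
            lines.append(f"Cohen's kappa          {f3(self.kappa.value)}")
        if self.odds is not None:
            lines.append(f"odds ratio             {f3(self.odds.value)}"
                         + (f"  [{self.odds.note}]" if self.odds.note else ""))
        lines += [
            "",
            f"verdict (alpha = {self.alpha}): {self.verdict.upper()}",
        ]
        if self.verdict_note:
            lines.append(f"  note: {self.verdict_note}")
        return "\n".join(lines)


def classify(
    table: ContingencyTable,
    sections: SectionMap | None = None,
    alpha: float = 0.05,
) -> str:
    """Verdict only: 'agreement', 'disagreement' or 'inconclusive'."""
    return InstrumentAgreement(table, sections, alpha=alpha).fit().verdict


def full_report(
    table: ContingencyTable,
    sections: SectionMap | None = None,
    alpha: float = 0.05,
    haldane: bool = False,
) -> AgreementResults:
    """All measures plus the verdict for one table (fitted results object)."""
    return InstrumentAgreement(table, sections, alpha=alpha, haldane=haldane).fit()
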