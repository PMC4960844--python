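"""Measure-comparison studies: diagonal sweeps and random-table simulations.

The diagonal sweep holds the total amount of agreement fixed while shifting
its split between positive-positive and negative-negative cells (off-diagonal
disagreement cells fixed at k), exposing how mutual information rewards
evenness of the agreement evidence where Cohen's kappa saturates.  The
random-table study draws seeded Dirichlet-multinomial 2x2 tables and records
every measure per table, for correlation and calibration analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classical import cohens_kappa, odds_ratio, pearson_correlation
from .contingency import ContingencyTable
from .information import mi_p_value, mutual_information

__all__ = [
    "SweepRecord",
    "RandomTableStudy",
    "diagonal_sweep",
    "k_grid",
    "random_table_study",
    "measure_correlation",
]


@dataclass(frozen=True)
class SweepRecord:
    x11: int
    x22: int
    k: int
    mutual_information: float
    kappa: float
    odds_ratio: float  # may be +inf


def _measures(x11: int, x22: int, k: int) -> SweepRecord:
    table = ContingencyTable(
        np.array([[x11, k], [k, x22]], dtype=float),
        ("positive", "negative"),
        ("positive", "negative"),
    )
    return SweepRecord(
        x11=x11,
        x22=x22,
        k=k,
        mutual_information=mutual_information(table),
        kappa=cohens_kappa(table).value,
        odds_ratio=odds_ratio(table).value,
    )


def diagonal_sweep(total: int, k: int = 1) -> list[SweepRecord]:
    """Sweep x11 = 1 .. total-1 with x22 = total - x11 and x12 = x21 = k."""
    if total < 2 or k < 1:
        raise ValueError("need total >= 2 and k >= 1")
    return [_measures(x11, total - x11, k) for x11 in range(1, total)]


def sweep_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.x11, r.x22, r.k, r.mutual_information, r.kappa, r.odds_ratio)
         for r in records],
        columns=["x11", "x22", "k", "mi", "kappa", "odds_ratio"],
    )


def k_grid(total: int, k_values: list[int]) -> dict[int, list[SweepRecord]]:
    """One diagonal sweep per disagreement level k."""
    return {int(k): diagonal_sweep(total, int(k)) for k in k_values}


def peak_records(grid: dict[int, list[SweepRecord]]) -> pd.DataFrame:
    """Per-k argmax of MI and kappa over the sweep (for plotting/analysis)."""
    rows = []
    for k, records in grid.items():
        mi_best = max(records, key=lambda r: r.mutual_information)
        ka_best = max(records, key=lambda r: r.kappa)
        rows.append((k, mi_best.x11, mi_best.mutual_information,
                     ka_best.x11, ka_best.kappa))
    return pd.DataFrame(
        rows, columns=["k", "mi_argmax_x11", "mi_peak", "kappa_argmax_x11", "kappa_peak"]
    )


@dataclass(frozen=True)
class RandomTableStudy:
    """Seeded Dirichlet-multinomial study of 2x2 tables and their measures."""

    seed: int
    n_tables: int
    n_per_table: int
    records: pd.DataFrame  # columns: mi, kappa, odds_ratio, log_or, p_mi, significant


def random_table_study(
    n_tables: int,
    n_per_table: int,
    seed: int,
    dirichlet_alpha=(1.0, 1.0, 1.0, 1.0),
    independence: bool = False,
    independence_marginals: tuple[float, float] = (0.5, 0.5),
) -> RandomTableStudy:
    """Draw seeded random 2x2 tables and record every measure per table.

    Cell probabilities come from a symmetric Dirichlet over the four cells
    (default alpha = 1, i.e. uniform on the simplex); with
    ``independence=True`` the cell probabilities are instead the product of
    fixed row/column marginals, giving an exact null for calibration.  Tables
    with a zero row or column marginal are resampled (they carry no
    information about association).
    """
    if n_tables < 2:
        raise ValueError("need n_tables >= 2")
    rng = np.random.default_rng(seed)
    probs_null = None
    if independence:
        pr, pc = independence_marginals
        probs_null = np.outer([pr, 1 - pr], [pc, 1 - pc]).ravel()
    rows = []
    resampled = 0
    while len(rows) < n_tables:
        p = probs_null if probs_null is not None else rng.dirichlet(dirichlet_alpha)
        counts = rng.multinomial(n_per_table, p).reshape(2, 2).astype(float)
        if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
            resampled += 1
            continue
        table = ContingencyTable(counts, ("positive", "negative"),
                                 ("positive", "negative"))
        sig = mi_p_value(table)
        orv = odds_ratio(table).value
        rows.append({
            "mi": mutual_information(table),
            "kappa": cohens_kappa(table).value,
            "odds_ratio": orv,
            "log_or": math.log(orv) if 0 < orv < math.inf else float("nan"),
            "p_mi": sig.p_value,
            "significant": sig.p_value < 0.05,
        })
    records = pd.DataFrame(rows)
    records.attrs["resampled"] = resampled
    return RandomTableStudy(seed=seed, n_tables=n_tables,
                            n_per_table=n_per_table, records=records)


def measure_correlation(study: RandomTableStudy) -> tuple[float, float, int]:
    """(r(log OR, MI), r(kappa, MI), n_finite_or).

    Tables with an infinite or undefined odds ratio are excluded from the
    first coefficient (their count is n_tables - n_finite_or) but kept for
    the kappa correlation.
    """
    rec = study.records
    finite = rec[np.isfinite(rec["log_or"])]
    if len(finite) < 3:
        raise ValueError("fewer than 3 tables with a finite log odds ratio")
    r_or = pearson_correlation(finite["log_or"], finite["mi"])
    r_kappa = pearson_correlation(rec["kappa"], rec["mi"])
    return r_or, r_kappa, int(len(finite))
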