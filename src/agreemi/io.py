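"""CSV I/O, run configuration and fixture generation.

Contingency CSV dialect: comma-separated, UTF-8; first row holds the column
labels (first cell empty or a caption), each following row holds the row
label then the counts.  Section-map CSVs share the shape and hold numeric
weights in [0, 1], or the tokens ``A`` (= 1) and ``D`` (= 0).  Score CSVs
hold one score per line with an optional header.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .contingency import (
    ContingencyTable,
    ScoreVector,
    SectionMap,
    TableValidationError,
)

__all__ = [
    "RunConfig",
    "read_contingency_csv",
    "write_contingency_csv",
    "read_section_csv",
    "read_scores_csv",
    "generate_fixtures",
    "PAPER_PRESET_TABLES",
]


@dataclass(frozen=True)
class RunConfig:
    """User-facing knobs shared by the CLI and scripted runs."""

    alpha: float = 0.05
    or_correction: bool = False  # Haldane-Anscombe +0.5 on the odds ratio
    dichotomize_rule: str = "ge"
    seed: int = 0
    output_format: str = "json"  # json | text | csv
    log_base: int = 2  # informational: all MI quantities are in bits

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.dichotomize_rule not in ("ge", "gt"):
            raise ValueError("dichotomize_rule must be 'ge' or 'gt'")
        if self.output_format not in ("json", "text", "csv"):
            raise ValueError("output_format must be json, text or csv")

    def to_dict(self) -> dict:
        return asdict(self)


def read_contingency_csv(path: str | Path) -> ContingencyTable:
    """Read a labelled count table; errors name the offending row/column."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise TableValidationError(f"{path}: empty or unparseable CSV") from exc
    if frame.empty:
        raise TableValidationError(f"{path}: no count rows found")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableValidationError(
            f"{path}: non-numeric cell at row '{frame.index[r]}', "
            f"column '{frame.columns[c]}'"
        )
    if (numeric < 0).any().any():
        r, c = np.argwhere((numeric < 0).to_numpy())[0]
        raise TableValidationError(
            f"{path}: negative count at row '{frame.index[r]}', "
            f"column '{frame.columns[c]}'"
        )
    return ContingencyTable.from_frame(numeric)


def write_contingency_csv(table: ContingencyTable, path: str | Path) -> None:
    frame = table.to_frame()
    # render integral counts without a trailing .0
    if float(frame.to_numpy().sum()).is_integer() and np.all(
        np.mod(frame.to_numpy(), 1) == 0
    ):
        frame = frame.astype(int)
    frame.to_csv(path)


def read_section_csv(path: str | Path) -> SectionMap:
    """Read a weight map; 'A' and 'D' tokens map to 1 and 0."""
    frame = pd.read_csv(path, index_col=0)
    def _token(value):
        if isinstance(value, str):
            stripped = value.strip()
            if stripped == "A":
                return 1.0
            if stripped == "D":
                return 0.0
        return value

    mapped = frame.map(_token).apply(pd.to_numeric, errors="coerce")
    if mapped.isna().any().any():
        r, c = np.argwhere(mapped.isna().to_numpy())[0]
        raise TableValidationError(
            f"{path}: unreadable weight at row '{frame.index[r]}', "
            f"column '{frame.columns[c]}' (use numbers in [0,1] or A/D tokens)"
        )
    return SectionMap(mapped.to_numpy(dtype=float))


def read_scores_csv(path: str | Path, scale_max: float | None = None) -> ScoreVector:
    raw = pd.read_csv(path, header=None).iloc[:, 0]
    values = pd.to_numeric(raw, errors="coerce")
    if values.isna().iloc[0] and len(values) > 1:  # tolerate a header line
        values = values.iloc[1:]
    if values.isna().any():
        raise TableValidationError(f"{path}: non-numeric score entries")
    return ScoreVector(values.to_numpy(dtype=float), scale_max=scale_max)


_BINARY = ("positive", "negative")

# the printed study tables: worked scenarios, the CAM vs FAM-CAM pilot table,
# the evened-agreement hypothetical and the sweep-peak anchor
PAPER_PRESET_TABLES: dict[str, list[list[int]]] = {
    "scenario1": [[10, 5], [5, 20]],
    "scenario2": [[5, 10], [20, 5]],
    "scenario3": [[5, 10], [5, 20]],
    "cam_famcam": [[8, 1], [1, 31]],
    "evened_agreement": [[20, 1], [1, 19]],
    "sweep_peak": [[499, 1], [1, 499]],
}


def generate_fixtures(preset: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a named set of fixture CSVs; returns the paths written.

    Presets: ``paper`` (the printed study tables, byte-stable), ``random``
    (seeded Dirichlet-multinomial tables) and ``independence`` (product-form
    expected counts for calibration checks).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, counts) -> None:
        table = ContingencyTable(np.asarray(counts, dtype=float), _BINARY, _BINARY)
        path = out_dir / f"{name}.csv"
        write_contingency_csv(table, path)
        written.append(path)

    if preset == "paper":
        for name, counts in PAPER_PRESET_TABLES.items():
            _write(name, counts)
        sections = pd.DataFrame([["A", "D"], ["D", "A"]],
                                index=_BINARY, columns=_BINARY)
        path = out_dir / "diagonal_sections.csv"
        sections.to_csv(path)
        written.append(path)
    elif preset == "random":
        rng = np.random.default_rng(seed)
        for i in range(6):
            while True:
                p = rng.dirichlet([1.0] * 4)
                counts = rng.multinomial(100, p).reshape(2, 2)
                if np.all(counts.sum(axis=0) > 0) and np.all(counts.sum(axis=1) > 0):
                    break
            _write(f"random_{i}", counts)
    elif preset == "independence":
        for i, (pr, pc, n) in enumerate([(0.5, 0.5, 200), (0.3, 0.6, 200),
                                         (0.2, 0.2, 500)]):
            expected = np.outer([pr, 1 - pr], [pc, 1 - pc]) * n
            _write(f"independence_{i}", expected)
    else:
        raise ValueError(f"unknown preset '{preset}' "
                         "(choose paper, random or independence)")
    return written
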