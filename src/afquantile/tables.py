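"""Lookup tables of quantile thresholds over prevalence x database-size grids.

Practitioners without scripting at hand can read the threshold ``Tv`` for
their disease straight from a precomputed table: rows are disease
prevalences (written both as ``1/n`` and as a decimal), columns are
database sizes in diploid individuals.  Cells hold the threshold frequency
``tv_count / 2c``; infeasible parameter combinations (the model would imply
everyone is affected) are rendered as ``NA`` rather than aborting the
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, TextIO

import pandas as pd

from .binomial import DEFAULT_LEVEL, DatabaseSpec, ThresholdResult, tv_threshold
from .models import (
    DiseaseModel,
    Inheritance,
    ModelInfeasibleError,
    Situation,
    allele_model,
)

__all__ = ["TableSpec", "ThresholdTable", "generate_table", "write_table"]

# default grids mirror the ranges a clinical user would consult: prevalences
# 1/1000 .. 1/100000 in steps of 1000, and the sizes of commonly used
# public panels (1000 Genomes phase 3 has 2504 individuals)
DEFAULT_PREVALENCES = tuple(1.0 / n for n in range(1000, 100001, 1000))
DEFAULT_DB_SIZES = (50, 100, 500, 1000, 2504, 5000, 10000)


@dataclass(frozen=True)
class TableSpec:
    """Grid specification for a threshold lookup table.

    Default situation is ``b`` (database restricted to non-diseased
    individuals), the realistic setting for consent-restricted public
    human panels.
    """

    inheritance: Inheritance
    prevalences: Sequence[float] = DEFAULT_PREVALENCES
    database_sizes: Sequence[int] = DEFAULT_DB_SIZES
    level: float = DEFAULT_LEVEL
    situation: Situation = Situation.B
    penetrance: float = 1.0
    detectance: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "inheritance", Inheritance.parse(self.inheritance))
        object.__setattr__(self, "situation", Situation.parse(self.situation))
        object.__setattr__(self, "prevalences", tuple(self.prevalences))
        object.__setattr__(self, "database_sizes", tuple(self.database_sizes))
        for name, grid in (("prevalences", self.prevalences),
                           ("database_sizes", self.database_sizes)):
            if not grid:
                raise ValueError(f"{name} grid is empty")
            diffs = [b - a for a, b in zip(grid, grid[1:])]
            if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs) or not diffs):
                raise ValueError(f"{name} grid must be strictly monotone")


@dataclass(frozen=True)
class ThresholdTable:
    """Computed lookup table: one :class:`ThresholdResult` (or None) per cell."""

    spec: TableSpec
    cells: tuple[tuple[Optional[ThresholdResult], ...], ...]  # [prevalence][size]

    def cell(self, prevalence_idx: int, size_idx: int) -> Optional[ThresholdResult]:
        return self.cells[prevalence_idx][size_idx]

    def frequencies(self) -> pd.DataFrame:
        """Threshold frequencies as a DataFrame (NaN where infeasible)."""
        data = [
            [cell.tv_frequency if cell is not None else float("nan") for cell in row]
            for row in self.cells
        ]
        return pd.DataFrame(
            data,
            index=pd.Index(self.spec.prevalences, name="prevalence"),
            columns=pd.Index(self.spec.database_sizes, name="individuals"),
        )

    def counts(self) -> pd.DataFrame:
        """Threshold allele counts as a DataFrame (pandas NA where infeasible)."""
        data = [
            [cell.tv_count if cell is not None else pd.NA for cell in row]
            for row in self.cells
        ]
        return pd.DataFrame(
            data,
            index=pd.Index(self.spec.prevalences, name="prevalence"),
            columns=pd.Index(self.spec.database_sizes, name="individuals"),
            dtype="Int64",
        )


def generate_table(spec: TableSpec) -> ThresholdTable:
    """Compute the threshold for every (prevalence, database size) cell.

    Infeasible cells (model construction or situation-b renormalization
    fails) become ``None`` instead of aborting the whole table.
    """
    rows = []
    for pd_ in spec.prevalences:
        row: list[Optional[ThresholdResult]] = []
        for size in spec.database_sizes:
            try:
                model = DiseaseModel(
                    prevalence=pd_,
                    inheritance=spec.inheritance,
                    penetrance=spec.penetrance,
                    detectance=spec.detectance,
                    situation=spec.situation,
                )
                am = allele_model(model)
                row.append(
                    tv_threshold(am.q_effective, DatabaseSpec(size), spec.level)
                )
            except ModelInfeasibleError:
                row.append(None)
        rows.append(tuple(row))
    return ThresholdTable(spec=spec, cells=tuple(rows))


def _prevalence_label(p: float) -> str:
    """Render a prevalence as '1/n' when it is (close to) a unit fraction."""
    frac = Fraction(p).limit_denominator(10**9)
    if frac.numerator == 1 and abs(1.0 / frac.denominator - p) < 1e-12 * p:
        return f"1/{frac.denominator}"
    return f"{p:.6g}"


def write_table(
    table: ThresholdTable, path: str | Path, format: str = "tsv"
) -> Path:
    """Write a lookup table to TSV or CSV.

    Header comment lines record the quantile level, inheritance mode,
    sampling situation, penetrance and detectance.  Each cell is written as
    ``frequency (count)`` with the frequency to 4 significant digits and the
    exact integer count, so the rounding of the printed frequency is never
    ambiguous.  Infeasible cells appear as ``NA`` with a footnote.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
    sep = "\t" if format == "tsv" else ","
    path = Path(path)
    spec = table.spec
    has_na = any(cell is None for row in table.cells for cell in row)
    with open(path, "w") as out:
        out.write(f"# level: {spec.level}\n")
        out.write(f"# inheritance: {spec.inheritance.value}\n")
        out.write(f"# situation: {spec.situation.value}\n")
        out.write(f"# penetrance: {spec.penetrance}\n")
        out.write(f"# detectance: {spec.detectance}\n")
        out.write("# cell format: threshold frequency (allele count)\n")
        header = ["prevalence", "prevalence_decimal"] + [
            f"c={size}" for size in spec.database_sizes
        ]
        out.write(sep.join(header) + "\n")
        for pd_, row in zip(spec.prevalences, table.cells):
            fields = [_prevalence_label(pd_), f"{pd_:.6g}"]
            for cell in row:
                if cell is None:
                    fields.append("NA")
                else:
                    fields.append(f"{cell.tv_frequency:.4g} ({cell.tv_count})")
            out.write(sep.join(fields) + "\n")
        if has_na:
            out.write(
                "# NA: model infeasible at this prevalence "
                "(implied affected fraction >= 1)\n"
            )
    return path


def read_table_frequencies(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Re-read a written table's threshold frequencies (round-trip helper)."""
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    sizes = [int(c.split("=", 1)[1]) for c in df.columns[2:]]
    values = df.iloc[:, 2:].map(
        lambda s: float("nan") if s == "NA" else float(str(s).split(" ")[0])
    )
    values.columns = pd.Index(sizes, name="individuals")
    values.index = pd.Index(df["prevalence_decimal"].astype(float), name="prevalence")
    return values
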