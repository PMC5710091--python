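"""Variant filtering (method 1) and variant flagging (method 2).

Filtering compares a candidate-variant list from a sequencing study against
a frequency-annotated variant database under one of three approaches:

* ``absence`` -- any candidate present in the database is removed;
* ``static`` -- candidates are removed when their database frequency
  strictly exceeds a fixed cutoff (conventionally 1% for autosomal
  recessive, 0.1% for autosomal dominant disorders);
* ``quantile`` -- the cutoff is the variable threshold ``Tv`` computed from
  the disease model and database size (see :mod:`afquantile.binomial`).

Flagging runs the model in the other direction: for each database variant
with a proposed disease model, the upper-tail probability
``P(Phi >= observed count)`` is computed; a small value marks the variant's
reported genotype-phenotype association as suspicious.

Databases and candidate lists are read from VCF (allele frequencies from
INFO ``AF``, or ``AC``/``AN``) or from a TSV frequency table with columns
``chrom, pos, ref, alt`` and ``count`` or ``frequency``.  Matching between
candidates and database records is exact on ``(chrom, pos, ref, alt)``
using VCF 1-based coordinates; indels are matched by literal ref/alt
strings with no left-alignment or normalization.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

import pandas as pd

from .binomial import (
    DEFAULT_ALPHA,
    DEFAULT_LEVEL,
    DatabaseSpec,
    ThresholdResult,
    flag_probability,
    frequency_to_count,
    tv_threshold,
)
from .models import DiseaseModel, Inheritance, allele_model

__all__ = [
    "Approach",
    "VariantRecord",
    "FilterDecision",
    "FlagDecision",
    "FlagReport",
    "FormatError",
    "load_database",
    "load_candidates",
    "filter_candidates",
    "flag_database_variants",
    "database_availability",
    "write_filter_report",
    "write_flag_report",
    "DEFAULT_STATIC_CUTOFFS",
]

# conventional static cutoffs: 1% for recessive, 0.1% for dominant disorders
DEFAULT_STATIC_CUTOFFS = {
    Inheritance.AUTOSOMAL_RECESSIVE: 0.01,
    Inheritance.AUTOSOMAL_DOMINANT: 0.001,
}


class FormatError(ValueError):
    """An input file is missing required fields or is malformed."""


class Approach(enum.Enum):
    ABSENCE = "absence"
    STATIC = "static"
    QUANTILE = "quantile"

    @classmethod
    def parse(cls, value: "Approach | str") -> "Approach":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(f"unknown filtering approach: {value!r}") from None


@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic variant, optionally with its database frequency.

    ``db_allele_count`` / ``db_frequency`` describe the variant's occurrence
    in the reference database; both may be absent for candidate records not
    found there.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None
    db_allele_count: Optional[int] = None
    db_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos is 1-based and must be >= 1, got {self.pos!r}")
        if self.db_allele_count is not None and self.db_allele_count < 0:
            raise ValueError(f"negative allele count: {self.db_allele_count!r}")
        if self.db_frequency is not None and not 0.0 <= self.db_frequency <= 1.0:
            raise ValueError(f"frequency outside [0, 1]: {self.db_frequency!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def frequency(self, chromosomes: Optional[int] = None) -> Optional[float]:
        """Best available frequency: explicit f, else count / chromosomes."""
        if self.db_frequency is not None:
            return self.db_frequency
        if self.db_allele_count is not None and chromosomes:
            return self.db_allele_count / chromosomes
        return None

    def count(self, db: DatabaseSpec) -> Optional[int]:
        """Best available allele count: explicit count, else round(f * 2c)."""
        if self.db_allele_count is not None:
            return self.db_allele_count
        if self.db_frequency is not None:
            return frequency_to_count(self.db_frequency, db)
        return None


@dataclass(frozen=True)
class FilterDecision:
    """Per-candidate outcome of one filtering approach, with its evidence."""

    variant: VariantRecord
    approach: Approach
    in_database: bool
    threshold_used: Optional[float]
    retained: bool
    rationale: str


@dataclass(frozen=True)
class FlagDecision:
    """Per-variant outcome of flagging, with the tail probability attached."""

    variant: VariantRecord
    observed_count: int
    tail_probability: float
    flagged: bool


@dataclass(frozen=True)
class FlagReport:
    """All flagging decisions for one run plus the number of tests performed.

    Tail probabilities are raw (no multiplicity adjustment); ``n_tests`` is
    surfaced so callers can apply their own correction across the batch.
    """

    decisions: tuple[FlagDecision, ...]
    model: DiseaseModel
    db: DatabaseSpec
    alpha: float
    q_effective: float

    @property
    def n_tests(self) -> int:
        return len(self.decisions)

    @property
    def n_flagged(self) -> int:
        return sum(d.flagged for d in self.decisions)


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("vcf", "tsv"):
            raise ValueError(f"format must be 'vcf' or 'tsv', got {fmt!r}")
        return fmt
    suffixes = "".join(path.suffixes).lower()
    return "vcf" if ".vcf" in suffixes else "tsv"


def _scalar_per_alt(value, n_alt: int, i: int):
    """INFO fields are scalars for bi-allelic sites, tuples for multi-allelic."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[i] if i < len(value) else None
    try:  # numpy arrays from cyvcf2
        if hasattr(value, "__len__") and n_alt > 1:
            return value[i]
    except TypeError:
        pass
    return value if (n_alt == 1 or i == 0) else None


def _load_vcf(path: Path, db: Optional[DatabaseSpec]) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    an_expected = db.chromosomes if db is not None else None
    an_warned = False
    vcf = VCF(str(path))
    try:
        for v in vcf:
            alts = v.ALT
            af_info = v.INFO.get("AF")
            ac_info = v.INFO.get("AC")
            an_info = v.INFO.get("AN")
            for i, alt in enumerate(alts):
                af = _scalar_per_alt(af_info, len(alts), i)
                ac = _scalar_per_alt(ac_info, len(alts), i)
                count = None
                freq = None
                if ac is not None and an_info:
                    an = int(an_info)
                    count = int(ac)
                    freq = count / an
                    if an_expected is not None and an != an_expected and not an_warned:
                        warnings.warn(
                            f"VCF AN={an} disagrees with the stated database size "
                            f"(2c={an_expected}); using AN from the file",
                            stacklevel=3,
                        )
                        an_warned = True
                elif af is not None:
                    freq = float(af)
                else:
                    raise FormatError(
                        f"{path}: record {v.CHROM}:{v.POS} {v.REF}>{alt} carries "
                        "neither INFO/AF nor INFO/AC+AN"
                    )
                records.append(
                    VariantRecord(
                        chrom=str(v.CHROM),
                        pos=int(v.POS),
                        ref=str(v.REF),
                        alt=str(alt),
                        id=v.ID,
                        db_allele_count=count,
                        db_frequency=freq,
                    )
                )
    finally:
        vcf.close()
    return records


def _load_tsv(path: Path, db: Optional[DatabaseSpec], *, require_freq: bool) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if df.empty and df.columns.size == 0:
        return []
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required TSV columns {sorted(missing)}")
    count_col = next((c for c in ("count", "allele_count", "ac") if c in df.columns), None)
    freq_col = next((c for c in ("frequency", "freq", "af") if c in df.columns), None)
    if require_freq and count_col is None and freq_col is None:
        raise FormatError(
            f"{path}: database TSV needs a 'count'/'allele_count' or "
            "'frequency' column"
        )
    chromosomes = db.chromosomes if db is not None else None
    records: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        row_d = row._asdict()
        count = None
        freq = None
        if count_col is not None and pd.notna(row_d[count_col]):
            count = int(row_d[count_col])
            if chromosomes:
                freq = count / chromosomes
        if freq_col is not None and pd.notna(row_d[freq_col]):
            freq = float(row_d[freq_col])
        if require_freq and count is None and freq is None:
            raise FormatError(
                f"{path}: record {row_d['chrom']}:{row_d['pos']} "
                f"{row_d['ref']}>{row_d['alt']} has neither a count nor a frequency"
            )
        rid = row_d.get("id")
        records.append(
            VariantRecord(
                chrom=str(row_d["chrom"]),
                pos=int(row_d["pos"]),
                ref=str(row_d["ref"]),
                alt=str(row_d["alt"]),
                id=None if rid is None or pd.isna(rid) else str(rid),
                db_allele_count=count,
                db_frequency=freq,
            )
        )
    return records


def load_database(
    path: str | Path,
    format: Optional[str] = None,
    db: Optional[DatabaseSpec] = None,
) -> list[VariantRecord]:
    """Read a frequency-annotated variant database from VCF or TSV.

    Multi-allelic VCF sites are decomposed into one record per alternate
    allele, each with its own frequency.  Records with frequency 0 (not
    segregating in the sampled population) are dropped.  When the VCF's
    ``AN`` disagrees with ``db.chromosomes`` a warning is issued and ``AN``
    takes precedence.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "vcf":
        records = _load_vcf(path, db)
    else:
        records = _load_tsv(path, db, require_freq=True)
    chromosomes = db.chromosomes if db is not None else None

    def segregating(r: VariantRecord) -> bool:
        f = r.frequency(chromosomes)
        if f is not None:
            return f > 0.0
        return (r.db_allele_count or 0) > 0

    return [r for r in records if segregating(r)]


def load_candidates(
    path: str | Path, format: Optional[str] = None
) -> list[VariantRecord]:
    """Read a candidate-variant list; frequency annotations are optional."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "vcf":
        from cyvcf2 import VCF

        records = []
        vcf = VCF(str(path))
        try:
            for v in vcf:
                for alt in v.ALT:
                    records.append(
                        VariantRecord(
                            chrom=str(v.CHROM), pos=int(v.POS),
                            ref=str(v.REF), alt=str(alt), id=v.ID,
                        )
                    )
        finally:
            vcf.close()
        return records
    return _load_tsv(path, None, require_freq=False)


def _resolve_threshold(
    approach: Approach,
    model: Optional[DiseaseModel],
    db: DatabaseSpec,
    static_cutoff: Optional[float],
    level: float,
) -> tuple[Optional[float], Optional[ThresholdResult]]:
    if approach is Approach.ABSENCE:
        return None, None
    if approach is Approach.STATIC:
        if static_cutoff is None:
            if model is None:
                raise ValueError(
                    "static approach needs a cutoff, or a model to pick the "
                    "conventional default (1% AR / 0.1% AD)"
                )
            static_cutoff = DEFAULT_STATIC_CUTOFFS[model.inheritance]
        return static_cutoff, None
    if model is None:
        raise ValueError("quantile approach requires a disease model")
    am = allele_model(model)
    result = tv_threshold(am.q_effective, db, level)
    return result.tv_frequency, result


def filter_candidates(
    candidates: Sequence[VariantRecord],
    database: Sequence[VariantRecord],
    approach: "Approach | str",
    model: Optional[DiseaseModel] = None,
    db: Optional[DatabaseSpec] = None,
    static_cutoff: Optional[float] = None,
    level: float = DEFAULT_LEVEL,
) -> list[FilterDecision]:
    """Apply one filtering approach to every candidate variant.

    A candidate is removed iff it matches a database record (exact
    ``(chrom, pos, ref, alt)``) whose frequency strictly exceeds the
    approach's threshold; candidates exactly at the threshold are retained.
    Under ``absence`` the threshold is conceptually 0, so any database match
    removes the candidate.  When a database record carries an allele count
    consistent with ``db``, the comparison is done on the count scale
    (``count > tv_count``), which avoids floating-point ties.
    """
    approach = Approach.parse(approach)
    if approach is not Approach.ABSENCE and db is None:
        raise ValueError("a DatabaseSpec is required for static/quantile filtering")
    if db is None:
        db = DatabaseSpec(individuals=1)  # chromosomes unused for absence
    threshold, tv = _resolve_threshold(approach, model, db, static_cutoff, level)
    by_key = {r.key: r for r in database}

    decisions = []
    for cand in candidates:
        hit = by_key.get(cand.key)
        if hit is None:
            decisions.append(
                FilterDecision(
                    variant=cand, approach=approach, in_database=False,
                    threshold_used=threshold, retained=True,
                    rationale="not present in database",
                )
            )
            continue
        f = hit.frequency(db.chromosomes)
        if approach is Approach.ABSENCE:
            retained = False
            why = "present in database (absence approach removes any match)"
        elif (
            tv is not None
            and hit.db_allele_count is not None
            and (
                hit.db_frequency is None
                or abs(hit.db_frequency - hit.db_allele_count / db.chromosomes)
                < 1.0 / (2 * db.chromosomes)
            )
        ):
            retained = not hit.db_allele_count > tv.tv_count
            why = (
                f"database count {hit.db_allele_count} "
                f"{'<=' if retained else '>'} Tv count {tv.tv_count}"
            )
        else:
            if f is None:
                raise FormatError(
                    f"database record {hit.key} lacks a usable frequency"
                )
            retained = not f > threshold
            why = f"database f={f:.6g} {'<=' if retained else '>'} threshold {threshold:.6g}"
        decisions.append(
            FilterDecision(
                variant=cand, approach=approach, in_database=True,
                threshold_used=threshold, retained=retained, rationale=why,
            )
        )
    return decisions


def flag_database_variants(
    database: Sequence[VariantRecord],
    model: DiseaseModel,
    db: DatabaseSpec,
    alpha: float = DEFAULT_ALPHA,
) -> FlagReport:
    """Flag database variants improbably frequent under a disease model.

    For every record the observed mutant-allele count is recovered (explicit
    count, or the rounding of ``f * 2c``) and the upper-tail probability
    ``P(Phi >= count)`` computed under ``Binomial(2c, q_eff)``.  Variants
    with tail probability ``<= alpha`` are flagged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    am = allele_model(model)
    decisions = []
    for rec in database:
        count = rec.count(db)
        if count is None:
            raise FormatError(f"database record {rec.key} has no count or frequency")
        tail = flag_probability(count, am.q_effective, db)
        decisions.append(
            FlagDecision(
                variant=rec,
                observed_count=count,
                tail_probability=tail.probability,
                flagged=tail.probability <= alpha,
            )
        )
    return FlagReport(
        decisions=tuple(decisions), model=model, db=db, alpha=alpha,
        q_effective=am.q_effective,
    )


def database_availability(
    database: Sequence[VariantRecord],
    threshold: float,
    db: Optional[DatabaseSpec] = None,
) -> float:
    """Fraction of database variants usable for filtering at a threshold.

    A database variant is "available" when its frequency strictly exceeds
    the threshold (only such variants can remove candidates).  At threshold
    0 this is 1.0 by construction for a database of segregating variants --
    the absence-approach uses the whole database.
    """
    if not database:
        raise ValueError("availability is undefined for an empty database")
    chromosomes = db.chromosomes if db is not None else None
    n_avail = 0
    for rec in database:
        f = rec.frequency(chromosomes)
        if f is None:
            raise FormatError(f"database record {rec.key} has no usable frequency")
        if f > threshold:
            n_avail += 1
    return n_avail / len(database)


def _write_summary_block(out: TextIO, pairs: Iterable[tuple[str, object]]) -> None:
    for key, value in pairs:
        out.write(f"# {key}: {value}\n")


def write_filter_report(
    decisions: Sequence[FilterDecision],
    out: TextIO,
    model: Optional[DiseaseModel] = None,
    db: Optional[DatabaseSpec] = None,
) -> None:
    """Write filtering decisions as TSV with a commented run-summary header."""
    summary: list[tuple[str, object]] = []
    if decisions:
        summary.append(("approach", decisions[0].approach.value))
        if decisions[0].threshold_used is not None:
            summary.append(("threshold", f"{decisions[0].threshold_used:.6g}"))
    if model is not None:
        summary += [
            ("prevalence", model.prevalence),
            ("inheritance", model.inheritance.value),
            ("penetrance", model.penetrance),
            ("detectance", model.detectance),
            ("situation", model.situation.value),
        ]
    if db is not None:
        summary += [("individuals", db.individuals), ("chromosomes", db.chromosomes)]
    _write_summary_block(out, summary)
    out.write("chrom\tpos\tref\talt\tid\tf\tin_database\tthreshold\tretained\trationale\n")
    chromosomes = db.chromosomes if db is not None else None
    for d in decisions:
        f = d.variant.frequency(chromosomes)
        out.write(
            "\t".join(
                [
                    d.variant.chrom,
                    str(d.variant.pos),
                    d.variant.ref,
                    d.variant.alt,
                    d.variant.id or ".",
                    "." if f is None else f"{f:.6g}",
                    str(d.in_database).lower(),
                    "." if d.threshold_used is None else f"{d.threshold_used:.6g}",
                    str(d.retained).lower(),
                    d.rationale,
                ]
            )
            + "\n"
        )


def write_flag_report(report: FlagReport, out: TextIO) -> None:
    """Write flagging decisions as TSV with a commented run-summary header."""
    _write_summary_block(
        out,
        [
            ("prevalence", report.model.prevalence),
            ("inheritance", report.model.inheritance.value),
            ("penetrance", report.model.penetrance),
            ("detectance", report.model.detectance),
            ("situation", report.model.situation.value),
            ("individuals", report.db.individuals),
            ("chromosomes", report.db.chromosomes),
            ("q_effective", f"{report.q_effective:.6g}"),
            ("alpha", report.alpha),
            ("n_tests", report.n_tests),
            ("n_flagged", report.n_flagged),
        ],
    )
    out.write("chrom\tpos\tref\talt\tid\tobserved_count\ttail_probability\tflagged\n")
    for d in report.decisions:
        out.write(
            "\t".join(
                [
                    d.variant.chrom,
                    str(d.variant.pos),
                    d.variant.ref,
                    d.variant.alt,
                    d.variant.id or ".",
                    str(d.observed_count),
                    f"{d.tail_probability:.6g}",
                    str(d.flagged).lower(),
                ]
            )
            + "\n"
        )
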