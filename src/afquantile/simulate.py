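"""Monte-Carlo validation of the filtering approaches and fixture generation.

The sampling model treats each of the ``2c`` database chromosomes as an
i.i.d. draw carrying the causal allele with probability ``q_eff`` (under
HWE, drawing ``2c`` alleles and drawing ``c`` genotypes give identical
allele-count distributions).  Repeated simulation of the causal variant's
database count lets us measure, per filtering approach, how often the
causal variant would be erroneously filtered out (the false-negative rate),
and how much of a simulated neutral variant spectrum stays available for
filtering.

Also provides the canonical toy dataset used throughout the documentation:
seven candidate variants, five of which sit in a 50-individual database,
with the causal variant at observed frequency 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binomial import DEFAULT_LEVEL, DatabaseSpec, tv_threshold
from .filtering import Approach, DEFAULT_STATIC_CUTOFFS
from .models import DiseaseModel, Situation, allele_model

__all__ = [
    "SimulationConfig",
    "ApproachSummary",
    "simulate_causal_counts",
    "evaluate_approaches",
    "make_fig1_fixture",
    "FIXTURE_MODEL",
    "FIXTURE_DB",
]

# toy-example study conditions: prevalence 1/10,000, autosomal recessive,
# full penetrance, whole-population sampling, 50-individual database
FIXTURE_MODEL = DiseaseModel(
    prevalence=1e-4, inheritance="AR", situation=Situation.A
)
FIXTURE_DB = DatabaseSpec(individuals=50)

# candidate variants of the toy example: (chrom, pos, ref, alt, database
# allele count out of 100 or None if absent from the database).  Only the
# causal variant's count (2/100 = 0.02, variant 4) is fixed by the study
# conditions; the neutral variants' counts are synthetic, chosen so the
# three approaches produce the canonical retain/filter pattern.
FIG1_VARIANTS: tuple[tuple[str, int, str, str, Optional[int]], ...] = (
    ("1", 101000, "A", "G", 25),   # variant 1: common polymorphism
    ("2", 202000, "C", "T", 10),   # variant 2
    ("3", 303000, "G", "A", 5),    # variant 3
    ("4", 404000, "T", "C", 2),    # variant 4: causal, f = 0.02
    ("5", 505000, "G", "C", 30),   # variant 5: common polymorphism
    ("6", 606000, "A", "T", None), # variant 6: absent from database
    ("7", 707000, "C", "G", None), # variant 7: absent from database
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one Monte-Carlo run.

    ``neutral_spectrum`` lists population frequencies of harmless variants
    used to measure how much of the database stays available for filtering.
    """

    model: DiseaseModel
    db: DatabaseSpec
    replicates: int = 100_000
    seed: int = 0
    neutral_spectrum: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates!r}")
        object.__setattr__(self, "neutral_spectrum", tuple(self.neutral_spectrum))


@dataclass(frozen=True)
class ApproachSummary:
    """Per-approach Monte-Carlo estimates."""

    approach: Approach
    threshold: Optional[float]
    false_negative_rate: float
    availability: Optional[float]


def simulate_causal_counts(config: SimulationConfig) -> np.ndarray:
    """Replicate draws of the causal variant's database allele count.

    Each replicate simulates one independently assembled database and
    returns ``Phi ~ Binomial(2c, q_eff)``; fixing the seed makes the run
    fully reproducible.
    """
    am = allele_model(config.model)
    rng = np.random.default_rng(config.seed)
    return rng.binomial(config.db.chromosomes, am.q_effective, size=config.replicates)


def evaluate_approaches(
    config: SimulationConfig,
    static_cutoff: Optional[float] = None,
    level: float = DEFAULT_LEVEL,
) -> pd.DataFrame:
    """Empirical false-negative rate and availability per filtering approach.

    A replicate counts as a false negative when the causal variant's sampled
    database frequency exceeds the approach's threshold (for the absence
    approach: when the causal allele appears at all, count > 0).
    Availability is the average fraction of the simulated neutral spectrum
    whose sampled frequency strictly exceeds the threshold -- those are the
    database variants an analyst could still use for filtering.
    """
    am = allele_model(config.model)
    n = config.db.chromosomes
    if static_cutoff is None:
        static_cutoff = DEFAULT_STATIC_CUTOFFS[config.model.inheritance]
    tv = tv_threshold(am.q_effective, config.db, level)

    counts = simulate_causal_counts(config)
    thresholds = {
        Approach.ABSENCE: (None, 0),
        Approach.STATIC: (static_cutoff, int(np.floor(static_cutoff * n))),
        Approach.QUANTILE: (tv.tv_frequency, tv.tv_count),
    }

    neutral_counts = None
    if config.neutral_spectrum:
        # one independently resampled database per replicate
        rng = np.random.default_rng((config.seed, 1))
        spectrum = np.asarray(config.neutral_spectrum)
        neutral_counts = rng.binomial(
            n, spectrum, size=(config.replicates, spectrum.size)
        )

    rows = []
    for approach, (freq_threshold, count_threshold) in thresholds.items():
        fn_rate = float(np.mean(counts > count_threshold))
        availability = None
        if neutral_counts is not None:
            if approach is Approach.ABSENCE:
                availability = 1.0  # whole database usable by definition
            else:
                availability = float(
                    np.mean(neutral_counts / n > freq_threshold)
                )
        rows.append(
            ApproachSummary(
                approach=approach,
                threshold=freq_threshold,
                false_negative_rate=fn_rate,
                availability=availability,
            )
        )
    return pd.DataFrame(
        {
            "approach": [r.approach.value for r in rows],
            "threshold": [r.threshold for r in rows],
            "false_negative_rate": [r.false_negative_rate for r in rows],
            "availability": [r.availability for r in rows],
        }
    )


def make_fig1_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the toy worked example as candidate/database TSVs plus a config.

    Emits ``candidates.tsv`` (7 variants), ``database.tsv`` (the 5 variants
    present in the 50-individual database, causal variant at count 2, f =
    0.02), ``model.yaml`` with the study conditions, and a short README
    explaining which values are fixed by the example and which are
    synthetic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": outdir / "candidates.tsv",
        "database": outdir / "database.tsv",
        "config": outdir / "model.yaml",
        "readme": outdir / "README.txt",
    }
    with open(paths["candidates"], "w") as out:
        out.write("chrom\tpos\tref\talt\tid\n")
        for i, (chrom, pos, ref, alt, _) in enumerate(FIG1_VARIANTS, start=1):
            out.write(f"{chrom}\t{pos}\t{ref}\t{alt}\tvariant_{i}\n")
    with open(paths["database"], "w") as out:
        out.write("chrom\tpos\tref\talt\tid\tcount\tfrequency\n")
        n = FIXTURE_DB.chromosomes
        for i, (chrom, pos, ref, alt, count) in enumerate(FIG1_VARIANTS, start=1):
            if count is None:
                continue
            out.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\tvariant_{i}\t{count}\t{count / n:.6g}\n"
            )
    with open(paths["config"], "w") as out:
        out.write(
            "prevalence: 1.0e-4\n"
            "inheritance: AR\n"
            "penetrance: 1.0\n"
            "detectance: 1.0\n"
            "situation: a\n"
            "individuals: 50\n"
        )
    with open(paths["readme"], "w") as out:
        out.write(
            "Toy worked example: 7 candidate variants from a sequencing study,\n"
            "5 of which are present in a 50-individual (100-chromosome) variant\n"
            "database. Variant 4 is the causal variant, at database frequency\n"
            "0.02 (count 2/100). The study conditions fix only variant 4's\n"
            "frequency and the retain/filter pattern; the neutral variants'\n"
            "frequencies (0.25, 0.10, 0.05, 0.30) are synthetic values chosen\n"
            "so that: the absence approach retains only the two variants absent\n"
            "from the database; the static 1% threshold also removes the causal\n"
            "variant (0.02 > 0.01); and the quantile threshold (Tv = 3/100 =\n"
            "0.03 at level 0.95) removes every neutral database variant while\n"
            "retaining the causal one (0.02 <= 0.03).\n"
        )
    return paths
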