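"""Binomial sampling model for mutant-allele counts in a variant database.

The number of copies of a mutant allele among the ``2c`` chromosomes of a
database of ``c`` diploid individuals is modelled as
``Phi ~ Binomial(2c, q_eff)``, where ``q_eff`` is the mutant-allele
frequency among the sampled individuals.  Two quantities drive everything
downstream:

* the threshold value ``Tv`` -- the smallest count ``k`` with
  ``P(Phi <= k) >= level`` (default level 0.95), reported both as a count
  and as the frequency ``k / 2c``; and
* the upper-tail probability ``P(Phi >= x)`` of an observed count ``x``,
  used to flag database-resident "disease-causing" variants whose observed
  frequency is improbably high under their proposed disease model.

All CDF evaluations go through scipy's regularized-incomplete-beta binomial
implementation; no normal or Poisson approximation is used anywhere, since
the regime of interest (tiny ``q``, large ``2c``) is exactly where such
approximations shift the threshold by whole counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom

__all__ = [
    "DatabaseSpec",
    "ThresholdResult",
    "TailProbability",
    "tv_threshold",
    "flag_probability",
    "frequency_to_count",
    "complex_joint_leq_prob",
    "DEFAULT_LEVEL",
    "DEFAULT_ALPHA",
]

DEFAULT_LEVEL = 0.95
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DatabaseSpec:
    """Size of a diploid variant database.

    ``individuals`` is the number of diploid individuals ``c``; the sampled
    chromosome count is ``2c``.
    """

    individuals: int

    def __post_init__(self) -> None:
        if not isinstance(self.individuals, int) or self.individuals < 1:
            raise ValueError(
                f"database must contain >= 1 diploid individual, got {self.individuals!r}"
            )

    @property
    def chromosomes(self) -> int:
        return 2 * self.individuals


@dataclass(frozen=True)
class ThresholdResult:
    """A quantile-based allele-count threshold and its frequency form."""

    q_effective: float
    chromosomes: int
    level: float
    tv_count: int
    tv_frequency: float


@dataclass(frozen=True)
class TailProbability:
    """Upper-tail probability of an observed mutant-allele count."""

    observed_count: int
    probability: float


def _check_probability(value: float, name: str, *, open_interval: bool = False) -> None:
    lo_ok = value > 0.0 if open_interval else value >= 0.0
    hi_ok = value < 1.0 if open_interval else value <= 1.0
    if not (lo_ok and hi_ok):
        bounds = "(0, 1)" if open_interval else "[0, 1]"
        raise ValueError(f"{name} must be in {bounds}, got {value!r}")


def tv_threshold(
    q_effective: float, db: DatabaseSpec, level: float = DEFAULT_LEVEL
) -> ThresholdResult:
    """Quantile-based threshold ``Tv`` for a database of known size.

    Returns the smallest count ``k`` with ``P(Phi <= k) >= level`` under
    ``Phi ~ Binomial(2c, q_effective)`` (the standard lower quantile), plus
    the corresponding frequency ``k / 2c``.  Database variants whose
    frequency strictly exceeds ``tv_frequency`` are considered safe to use
    for filtering candidate variants.
    """
    _check_probability(q_effective, "q_effective")
    _check_probability(level, "level", open_interval=True)
    n = db.chromosomes
    tv_count = int(binom.ppf(level, n, q_effective))
    return ThresholdResult(
        q_effective=q_effective,
        chromosomes=n,
        level=level,
        tv_count=tv_count,
        tv_frequency=tv_count / n,
    )


def flag_probability(
    observed_count: int, q_effective: float, db: DatabaseSpec
) -> TailProbability:
    """Probability of seeing at least ``observed_count`` mutant alleles.

    ``P(Phi >= x) = 1 - P(Phi <= x - 1)``.  A small value means the variant
    sits in the database at a frequency improbably high under the proposed
    disease model, and its reported genotype-phenotype link deserves
    re-examination.
    """
    _check_probability(q_effective, "q_effective")
    n = db.chromosomes
    if not 0 <= observed_count <= n:
        raise ValueError(
            f"observed_count must be in [0, {n}] (the chromosome count), "
            f"got {observed_count!r}"
        )
    if observed_count == 0:
        prob = 1.0
    else:
        prob = float(binom.sf(observed_count - 1, n, q_effective))
    return TailProbability(observed_count=observed_count, probability=prob)


def frequency_to_count(f: float, db: DatabaseSpec) -> int:
    """Integer allele count underlying a published database frequency.

    Database allele frequencies are discretizations of counts over ``2c``
    chromosomes; this recovers ``round(f * 2c)`` with ties rounded away
    from zero, so a printed ``f = 0.0004`` over 5,008 chromosomes maps back
    to the count 2 it came from.
    """
    _check_probability(f, "frequency")
    return int(math.floor(f * db.chromosomes + 0.5))


def complex_joint_leq_prob(
    q: float, db: DatabaseSpec, tv_count: int, k_loci: int
) -> float:
    """Joint probability that ``k_loci`` independent loci all stay <= Tv.

    ``P(Phi <= tv_count)**k_loci``.  An approximation for complex disorders
    only: it assumes the loci are independent, that each follows the same
    binomial model, and that the number of contributing loci is known --
    none of which hold exactly.  For Mendelian models use the single-locus
    quantities directly.
    """
    _check_probability(q, "q")
    if k_loci < 1:
        raise ValueError(f"k_loci must be >= 1, got {k_loci!r}")
    if not 0 <= tv_count <= db.chromosomes:
        raise ValueError(
            f"tv_count must be in [0, {db.chromosomes}], got {tv_count!r}"
        )
    single = float(binom.cdf(tv_count, db.chromosomes, q))
    return single**k_loci
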