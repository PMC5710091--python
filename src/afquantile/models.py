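"""Disease models linking population prevalence to mutant-allele frequency.

Under Hardy-Weinberg equilibrium a bi-allelic locus with wild-type allele
frequency ``p`` and mutant-allele frequency ``q`` (``p + q = 1``) has
genotype frequencies ``p**2 + 2*p*q + q**2 = 1``.  Given a disease
prevalence ``Pd`` (per-individual risk of being diseased), a mode of
inheritance, a penetrance ``Ppt = P(phenotype | genotype)`` and a detectance
``Pdt = P(genotype | phenotype)`` (the fraction of cases attributable to the
locus under study), the population mutant-allele frequency ``q`` follows in
closed form:

* autosomal recessive: ``q = sqrt(D)``
* autosomal dominant:  ``q = 1 - sqrt(1 - D)``

where ``D = Pd * Pdt / Ppt`` is the per-locus fraction of genetically
affected individuals.  With full penetrance and no genetic heterogeneity
(``Ppt = Pdt = 1``) these reduce to ``q = sqrt(Pd)`` and
``q = 1 - sqrt(1 - Pd)``.

Public variant databases are often restricted to individuals without the
disease under study (consent criteria exclude cases).  The module therefore
distinguishes two sampling situations: ``a`` -- individuals are drawn at
random from the whole population -- and ``b`` -- individuals are drawn only
from the non-diseased part, which depletes the mutant allele.  Situation b
replaces ``q`` by the mutant-allele frequency among non-diseased individuals
(``q'``), obtained by renormalizing the HWE genotype frequencies over the
non-diseased stratum.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Inheritance",
    "Situation",
    "DiseaseModel",
    "GenotypeFrequencies",
    "AlleleModel",
    "ModelInfeasibleError",
    "q_from_prevalence",
    "genotype_freqs",
    "effective_sampling_freq",
    "prevalence_from_q",
    "allele_model",
    "prevalence_upper_bound",
]


class ModelInfeasibleError(ValueError):
    """The disease-model parameters imply an impossible population.

    Raised when the implied fraction of genetically affected individuals
    reaches or exceeds 1 (``Pd * Pdt / Ppt >= 1``), or when situation-b
    renormalization would divide by a non-positive non-diseased fraction.
    """


class Inheritance(enum.Enum):
    """Autosomal mode of inheritance."""

    AUTOSOMAL_DOMINANT = "AD"
    AUTOSOMAL_RECESSIVE = "AR"

    @classmethod
    def parse(cls, value: "Inheritance | str") -> "Inheritance":
        if isinstance(value, cls):
            return value
        key = str(value).strip().upper()
        aliases = {
            "AD": cls.AUTOSOMAL_DOMINANT,
            "AUTOSOMAL_DOMINANT": cls.AUTOSOMAL_DOMINANT,
            "DOMINANT": cls.AUTOSOMAL_DOMINANT,
            "AR": cls.AUTOSOMAL_RECESSIVE,
            "AUTOSOMAL_RECESSIVE": cls.AUTOSOMAL_RECESSIVE,
            "RECESSIVE": cls.AUTOSOMAL_RECESSIVE,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown inheritance mode: {value!r}") from None


class Situation(enum.Enum):
    """How database individuals were sampled from the population.

    ``A``: at random from the entire population.  ``B``: only from the
    non-diseased part of the population (e.g. consent-restricted cohorts).
    """

    A = "a"
    B = "b"

    @classmethod
    def parse(cls, value: "Situation | str") -> "Situation":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unknown sampling situation: {value!r}") from None


@dataclass(frozen=True)
class DiseaseModel:
    """Epidemiological prior for one candidate disease locus.

    Parameters
    ----------
    prevalence:
        Per-individual disease risk ``Pd``, in the open interval (0, 1).
        If an epidemiological source gives a range, pass the upper bound
        (see :func:`prevalence_upper_bound`).
    inheritance:
        :class:`Inheritance` or one of the strings ``"AR"``/``"AD"``.
    penetrance:
        ``Ppt = P(phenotype | genotype)``, in (0, 1]; default 1 (fully
        penetrant).
    detectance:
        ``Pdt = P(genotype | phenotype)``, in (0, 1]; default 1 (no genetic
        heterogeneity -- all cases attributable to this locus).
    situation:
        :class:`Situation` or ``"a"``/``"b"``; default ``"a"``.
    """

    prevalence: float
    inheritance: Inheritance
    penetrance: float = 1.0
    detectance: float = 1.0
    situation: Situation = Situation.A

    def __post_init__(self) -> None:
        object.__setattr__(self, "inheritance", Inheritance.parse(self.inheritance))
        object.__setattr__(self, "situation", Situation.parse(self.situation))
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(
                f"prevalence must be in (0, 1), got {self.prevalence!r}"
            )
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError(
                f"penetrance must be in (0, 1], got {self.penetrance!r}"
            )
        if not 0.0 < self.detectance <= 1.0:
            raise ValueError(
                f"detectance must be in (0, 1], got {self.detectance!r}"
            )
        if self.locus_affected_fraction >= 1.0:
            raise ModelInfeasibleError(
                "infeasible disease model: prevalence * detectance / penetrance "
                f"= {self.locus_affected_fraction:.6g} >= 1 implies every "
                "individual is genetically affected at this locus"
            )

    @property
    def locus_affected_fraction(self) -> float:
        """``D = Pd * Pdt / Ppt``: fraction genetically affected at this locus."""
        return self.prevalence * self.detectance / self.penetrance


@dataclass(frozen=True)
class GenotypeFrequencies:
    """HWE genotype frequencies (wild-type hom, het, mutant hom)."""

    hom_wild: float
    het: float
    hom_mut: float

    def __post_init__(self) -> None:
        total = self.hom_wild + self.het + self.hom_mut
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"genotype frequencies sum to {total!r}, not 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.hom_wild, self.het, self.hom_mut)


@dataclass(frozen=True)
class AlleleModel:
    """Population allele frequency and the effective sampling frequency.

    ``q_effective`` is the binomial success probability used downstream:
    equal to ``q_population`` under situation a, and to the non-diseased
    stratum frequency ``q'`` under situation b.
    """

    q_population: float
    q_effective: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_effective <= self.q_population <= 1.0:
            raise ValueError(
                "require 0 <= q_effective <= q_population <= 1, got "
                f"q_effective={self.q_effective!r}, q_population={self.q_population!r}"
            )


def q_from_prevalence(model: DiseaseModel) -> float:
    """Population mutant-allele frequency ``q`` implied by a disease model.

    Inverts the forward HWE prevalence model for the per-locus affected
    fraction ``D = Pd * Pdt / Ppt``:

    * AR: ``Pd_locus = q**2``  =>  ``q = sqrt(D)``
    * AD: ``Pd_locus = 2*p*q + q**2 = 1 - (1-q)**2``  =>  ``q = 1 - sqrt(1 - D)``

    Raises
    ------
    ModelInfeasibleError
        If ``D >= 1`` (already rejected at model construction).
    """
    d = model.locus_affected_fraction
    if model.inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
        return math.sqrt(d)
    return 1.0 - math.sqrt(1.0 - d)


def genotype_freqs(q: float) -> GenotypeFrequencies:
    """HWE genotype frequencies ``(p**2, 2*p*q, q**2)`` with ``p = 1 - q``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {q!r}")
    p = 1.0 - q
    return GenotypeFrequencies(hom_wild=p * p, het=2.0 * p * q, hom_mut=q * q)


def effective_sampling_freq(q: float, model: DiseaseModel) -> float:
    """Mutant-allele frequency among the individuals eligible for sampling.

    Situation a returns ``q`` unchanged.  Situation b conditions the HWE
    genotype distribution on being non-diseased (each genetically affected
    genotype is diseased with probability ``Ppt``) and recomputes the
    mutant-allele frequency in that stratum:

    * AR: ``q' = (p*q + q**2 * (1 - Ppt)) / (1 - Ppt * q**2)``
    * AD: ``q' = q * (1 - Ppt) / (1 - Ppt * (2*p*q + q**2))``

    At full penetrance these reduce to ``q' = q / (1 + q)`` (AR: affected
    homozygotes excluded) and ``q' = 0`` (AD: every carrier excluded).
    Cases at other loci are treated as a negligible fraction of the excluded
    pool, consistent with the mutually-exclusive-loci approximation.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {q!r}")
    if model.situation is Situation.A:
        return q
    p = 1.0 - q
    ppt = model.penetrance
    if model.inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
        denom = 1.0 - ppt * q * q
    else:
        denom = 1.0 - ppt * (2.0 * p * q + q * q)
    if denom <= 0.0:
        raise ModelInfeasibleError(
            "situation-b renormalization impossible: the whole population is "
            f"diseased (non-diseased fraction {denom:.6g})"
        )
    if model.inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
        return (p * q + q * q * (1.0 - ppt)) / denom
    return q * (1.0 - ppt) / denom


def prevalence_from_q(q: float, model: DiseaseModel) -> float:
    """Forward model: disease prevalence implied by allele frequency ``q``.

    Exact inverse of :func:`q_from_prevalence`:
    AR ``Pd = Ppt * q**2 / Pdt``; AD ``Pd = Ppt * (2*p*q + q**2) / Pdt``.
    The ``prevalence`` field of *model* is ignored; only inheritance,
    penetrance and detectance are used.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {q!r}")
    if model.inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
        affected = q * q
    else:
        p = 1.0 - q
        affected = 2.0 * p * q + q * q
    return model.penetrance * affected / model.detectance


def allele_model(model: DiseaseModel) -> AlleleModel:
    """Convenience: population ``q`` and effective sampling frequency together."""
    q = q_from_prevalence(model)
    return AlleleModel(q_population=q, q_effective=effective_sampling_freq(q, model))


def prevalence_upper_bound(low: float, high: float) -> float:
    """Resolve a prevalence range to the value the threshold model should use.

    The conservative convention is to use the upper bound of a published
    prevalence range: a higher prevalence yields a higher threshold, which
    protects against erroneously discarding the causal variant.
    """
    if not 0.0 < low <= high < 1.0:
        raise ValueError(f"invalid prevalence range ({low!r}, {high!r})")
    return high
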