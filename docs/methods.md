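# Methods

## The problem

Rare-disease sequencing studies produce long candidate-variant lists that
are routinely pruned against public variant databases (1000 Genomes,
gnomAD, ...). Two pruning conventions dominate: remove any candidate
present in the database at all (the *absence* approach), or remove
candidates above a static frequency cutoff (1% for autosomal recessive,
0.1% for autosomal dominant disorders). Both ignore that databases are
*contaminated*: true disease-causing alleles do appear in them, at rates
governed by the disease's own epidemiology. The absence approach then
discards the causal variant whenever it was sampled even once; a static
cutoff is simultaneously too strict for common recessive diseases and too
lax for very rare ones.

This package replaces the fixed rule with a *variable* threshold derived
from the disease model, and runs the same model in reverse to flag
database-resident "pathogenic" variants whose observed frequency is
implausibly high for their claimed disease model.

## Model

A bi-allelic causal locus in Hardy-Weinberg equilibrium has mutant-allele
frequency `q` and genotype frequencies `p², 2pq, q²` (`p = 1 − q`). Writing
`Pd` for the disease prevalence, `Ppt = P(phenotype | genotype)` for
penetrance and `Pdt = P(genotype | phenotype)` for detectance (the fraction
of cases attributable to this locus; `Pdt = 1` means no genetic
heterogeneity), the fraction of individuals genetically affected *at this
locus* is

    D = Pd · Pdt / Ppt,          feasible only when D < 1.

Inverting the HWE forward model gives the population allele frequency:

    autosomal recessive:  q = √D
    autosomal dominant:   q = 1 − √(1 − D)

At equal prevalence the dominant allele is far rarer than the recessive
one, because a single copy suffices to cause disease.

**Sampling situations.** Databases assembled from the whole population
(situation *a*) see the allele at frequency `q`. Databases restricted to
non-diseased individuals (situation *b*, the realistic case for
consent-restricted panels) see it at the frequency of the non-diseased
stratum, obtained by down-weighting each genetically affected genotype by
`Ppt` and renormalizing:

    AR: q′ = (pq + q²(1 − Ppt)) / (1 − Ppt·q²)
    AD: q′ = q(1 − Ppt) / (1 − Ppt·(2pq + q²))

At full penetrance these collapse to `q′ = q/(1+q)` (AR; affected
homozygotes excluded, heterozygous carriers remain) and `q′ = 0` (AD; every
carrier is affected and excluded). When heterogeneity is present the
renormalization uses only the locus-specific affected fraction, treating
cases at other loci as a negligible share of the excluded pool; this is the
standard mutually-exclusive-loci approximation for rare diseases, and the
package treats it as exact. The reduced-penetrance situation-b formulas are
derived here from first principles by conditional renormalization of the
HWE genotype table; the test suite verifies them against direct stratum
enumeration and against the classical full-penetrance limits.

**The threshold.** The mutant-allele count `Φ` among the `2c` chromosomes
of a database of `c` diploid individuals is `Binomial(2c, q_eff)` with
`q_eff = q` (situation a) or `q′` (situation b), assuming i.i.d. sampling
and no sequencing error. The threshold `Tv` is the standard lower quantile

    Tv = min { k : P(Φ ≤ k) ≥ level },     level = 0.95 by default,

reported both as the integer count and the frequency `Tv/2c`. Only database
variants with frequency *strictly above* `Tv/2c` are used to remove
candidates, so the causal variant is erroneously filtered with probability
at most `1 − level`, by construction. Because discarding the causal variant
ends the search while a few extra false positives are merely inconvenient,
the method is deliberately asymmetric in favour of sensitivity.

**Flagging.** For a database variant with observed count `x` (or published
frequency `f`, mapped to the count `round(f · 2c)`, ties away from zero)
and a proposed disease model, the tail probability `P(Φ ≥ x)` measures how
surprising the observation is under that model. Values at or below `α`
(default 0.05) flag the variant's genotype-phenotype claim for
re-examination. Tail probabilities are reported raw; the number of tests in
the batch is included in the report so callers can apply their own
multiplicity correction.

**Complex disorders.** `complex_joint_leq_prob` exposes the product
approximation `P(Φ ≤ Tv)^k` for `k` independent common loci. It is a rough
device only — it assumes independence, a shared `q`, and a known locus
count — and is not used by any filtering path.

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `level` | quantile level for `Tv` | 0.95 | accepts a 5% risk of discarding the causal variant |
| `alpha` | flagging significance | 0.05 | complements the 95% quantile |
| `penetrance` | `P(phenotype \| genotype)` | 1 | fully penetrant unless known otherwise |
| `detectance` | `P(genotype \| phenotype)` | 1 | locus count generally unknown a priori, so no heterogeneity is assumed |
| `situation` | sampling stratum | `a` (library), `b` (lookup tables) | tables target public human panels, which exclude cases |
| static cutoffs | 1% (AR), 0.1% (AD) | convention | the rule-of-thumb the variable threshold replaces |

Prevalence ranges are resolved to their upper bound: overestimating `Pd`
raises `Tv`, which errs on the side of keeping the causal variant.

## Numerical choices

* Binomial CDF, quantile and survival functions are evaluated with scipy's
  regularized-incomplete-beta implementation; no normal or Poisson
  approximation anywhere. The regime of interest (q ~ 1e-3, 2c ~ 5e3) is
  exactly where a Poisson error shifts `Tv` by whole counts.
* The quantile convention is "smallest k with CDF(k) ≥ level". The toy
  worked example (q = 0.01, 2c = 100 → Tv = 3) discriminates this from the
  alternative "largest k with CDF(k) < level" convention.
* Frequency/count duality: published database frequencies are
  discretizations of counts. When a record carries a count consistent with
  the stated database size, filtering compares counts (`count > tv_count`),
  avoiding floating-point ties; otherwise it compares frequencies, with
  removal requiring strict exceedance in either representation.
* `D → 1` raises an explicit infeasibility error rather than silently
  returning `q → 1`; infeasible lookup-table cells render as `NA` without
  aborting the table.
* Matching between candidates and database records is exact on
  `(chrom, pos, ref, alt)` with VCF 1-based coordinates; indels are not
  left-aligned or normalized (a documented limitation). Multi-allelic VCF
  sites are decomposed into one record per alternate allele; records with
  frequency 0 are dropped as non-segregating. When a VCF's `AN` disagrees
  with the stated database size, `AN` takes precedence with a warning.

## Synthetic data and what it shows

`afquantile.simulate` draws the causal variant's database count directly as
`Binomial(2c, q_eff)` — under HWE, drawing `2c` alleles i.i.d. and drawing
`c` genotypes give identical allele-count distributions. The Monte-Carlo
harness measures each approach's empirical false-negative rate (causal
variant sampled above the approach's threshold) and the availability of a
user-supplied neutral frequency spectrum. The toy fixture
(`make_fig1_fixture`) writes seven candidates, five of them in a
50-individual database with the causal variant at f = 0.02; only the causal
variant's frequency and the retain/filter pattern are fixed by the worked
example, the neutral frequencies (0.25, 0.10, 0.05, 0.30) are synthetic
choices documented in the fixture's README.

The generator emulates ideal sampling only: no linkage structure, no
population stratification, no sequencing error or allelic drop-out, exact
HWE. Passing simulations therefore validate the *calibration of the
threshold under its own model assumptions*, not robustness to violated
assumptions in real cohorts — prevalence misestimates, penetrance
surprises and population mismatch all shift real-world performance, and the
flagging method exists precisely because such deviations happen.

Default Monte-Carlo problem sizes: 1e5 replicates per configuration over a
grid of prevalences {1e-3 … 1e-6}, database sizes {50, 500, 2504} and both
sampling situations; vectorized draws make the whole grid a matter of
seconds, so the defaults are run as-is in the test suite.

## Design choices where the design was open

* **Heterogeneity composition.** Detectance enters as a multiplicative
  reduction of per-locus prevalence (`D = Pd·Pdt/Ppt`), with the
  mutually-exclusive-loci approximation taken as exact.
* **Lookup-table grids.** Prevalences `1/n` for n = 1000…100000 in steps of
  1000; sizes {50, 100, 500, 1000, 2504, 5000, 10000} (2504 being the 1000
  Genomes phase-3 panel). Both are overridable; the defaults are this
  package's own choice. Tables default to situation b because the public
  panels they target exclude cases.
* **Cell rendering.** Table cells carry the frequency to 4 significant
  digits *and* the exact integer count, so the rounding of a printed
  frequency is never ambiguous.
* **No multiplicity correction in flagging.** Flagging reports raw tail
  probabilities plus the test count; correction policy is the caller's.

## Known limitations

* Autosomal modes only; X-linked and compound-heterozygote models are out
  of scope, as are non-HWE populations and multi-allelic disease models.
* No variant normalization or liftover: records must share coordinate
  conventions with the database.
* Population matching is the user's responsibility — the model assumes the
  prevalence estimate and the database describe the same population.
* Situation-b formulas ignore the (tiny) depletion caused by cases at
  *other* loci of a heterogeneous disease.
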