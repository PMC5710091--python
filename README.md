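# afquantile

Quantile-based allele-frequency thresholds for variant filtering and
flagging in Mendelian disease studies.

## Why

Candidate variants from rare-disease sequencing are routinely filtered
against public variant databases, either by discarding every candidate the
database contains (*absence* approach) or by a static frequency cutoff (1%
for autosomal recessive, 0.1% for autosomal dominant). Both rules ignore
that databases contain true disease-causing alleles — *database
contamination* — so the causal variant itself can be filtered away.

`afquantile` computes a **variable threshold** from the disease's
epidemiology instead. Given prevalence `Pd`, mode of inheritance,
penetrance `Ppt`, detectance `Pdt` and how the database was sampled, the
expected population allele frequency is (with `D = Pd·Pdt/Ppt`):

    AR: q = √D           AD: q = 1 − √(1 − D)

optionally adjusted to the non-diseased stratum `q′` when the database
excludes cases. The mutant-allele count among the database's `2c`
chromosomes is `Φ ~ Binomial(2c, q)`, and the threshold is the 95% quantile

    Tv = min { k : P(Φ ≤ k) ≥ 0.95 },

so the causal variant exceeds `Tv` — and is erroneously removed — with
probability at most 5%. The same model run in reverse computes
`P(Φ ≥ observed count)` for database-resident "pathogenic" variants and
flags those whose frequency is implausibly high under their claimed disease
model. See `docs/methods.md` for the full model, assumptions and defaults.

## Worked example

A disease with prevalence 1 in 10,000, autosomal recessive, fully
penetrant, against a database of 50 individuals sampled from the whole
population:

```sh
$ afquantile threshold --prevalence 1/10000 --inheritance AR \
      --individuals 50 --situation a
q_population    0.01
q_effective     0.01
chromosomes     100
level           0.95
tv_count        3
tv_frequency    0.03
```

The recessive model turns the prevalence into a carrier-allele frequency of
`q = √(1/10000) = 0.01`; across 100 database chromosomes the 95% binomial
quantile is 3 copies, i.e. a threshold frequency of 0.03. A causal variant
observed in the database at f = 0.02 (2/100) — above its expected 0.01 due
to sampling noise — survives quantile filtering but would be lost to both
the absence approach and the static 1% cutoff.

Is that observed frequency suspicious? Running the model in reverse:

```sh
$ afquantile flag --count 2 --prevalence 1/10000 --inheritance AR \
      --individuals 50 --situation a
q_effective       0.01
observed_count    2
tail_probability  0.2642
flagged           false
```

Two or more copies occur with probability 0.26 under the model — no
evidence against it.

For a very rare recessive disease (prevalence 1 in 1,000,000) filtered
against a 2,504-individual panel that excludes affected individuals
(situation b):

```sh
$ afquantile threshold --prevalence 1e-6 --inheritance AR \
      --individuals 2504 --situation b
q_population    0.001
q_effective     0.000999
chromosomes     5008
level           0.95
tv_count        9
tv_frequency    0.001797
```

A known pathogenic variant present at f = 0.0004 sits well below this
Tv ≈ 0.0018 and is retained, where the absence approach would have
discarded it.

Other subcommands: `filter` (batch-filter a VCF/TSV candidate list against
a VCF/TSV database), `flag-db` (flag every database variant), `table`
(Tv lookup tables over prevalence × database-size grids), `simulate`
(Monte-Carlo false-negative/availability assessment) and `fixture` (emit
the built-in toy dataset). All of these are thin wrappers over the
`afquantile` Python API (`DiseaseModel`, `tv_threshold`,
`filter_candidates`, `flag_database_variants`, ...).

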