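# Methods

## The problem

In a closed, individually monitored population with a multi-generation
pedigree, haplotype frequencies change from year to year even without
selection: Mendelian segregation through a finite pedigree is genetic
drift. Asking whether an observed frequency trajectory is evidence of
selection therefore requires a null distribution of trajectories *given
that pedigree* — who bred with whom, when, and how long each animal
lived. The gene-drop provides exactly that: it repeatedly re-transmits
haplotypes down the fixed pedigree and tabulates the resulting
standing-population frequency trajectories.

`haplodrop` implements this for intact multi-locus MHC haplotypes (no
recombination or mutation within the block, no immigration), together
with the haplotype-level descriptors used in fitness analyses (dosage,
heterozygosity, amino-acid divergence) and the post-processing of
fitness-model coefficients (Wald tests and haplotype-vs-rest contrasts).

## Gene-drop model

Let the founder window be the earliest genotyped birth cohorts (default
1989–1992) and the simulated window the later cohorts (default
1993–2012). Per replicate:

1. Individuals born in or before the founder window keep their observed
   diplotypes verbatim.
2. Every other individual receives one allele per parental slot:
   a Mendelian draw (each of the parent's two haplotypes with
   probability 1/2) when the parent is in the pedigree, otherwise a draw
   from the observed haplotype frequencies of the individual's own birth
   cohort. Individuals born in the simulated window are always
   re-simulated, even when genotyped — copying their observed genotypes
   would leak the signal under test into the null.
3. Standing-population frequencies are tabulated per calendar year over
   the individuals alive that year. The life interval is inclusive on
   both ends; an individual with unknown death year counts only in its
   birth year unless a last-seen (`FINAL_YEAR`) column says otherwise.

Cohort frequencies are computed once from the observed data and held
fixed across replicates; a cohort without genotyped members borrows the
nearest genotyped cohort (earlier on ties), and this fallback is logged.

By default (`frequency_individuals="genotyped_only"`) simulated
frequencies are computed over the same individual set as the observed
trajectory — those with observed diplotypes — so the two series differ
only in genotype, never in composition. The alternative `"all"` uses
every individual alive, all of whom carry simulated genotypes.

**Expectation conservation.** Mendelian transmission preserves
expectations: a child's expected frequency vector is the mean of its two
allele sources. `expected_frequency_trajectory` propagates this in
closed form down the pedigree and provides an exact oracle for the
Monte-Carlo mean. Note that this expectation is the *founder-contribution-
weighted* frequency, not the founder-cohort frequency: founders with
more descendants weigh more, and on realistic pedigrees the two differ
substantially.

## Trajectory statistics and tests

Per haplotype, over the simulated-year window:

* slope: OLS slope of frequency on calendar year (unweighted; undefined
  years dropped, never interpolated);
* cumulative change: sum of absolute consecutive-year differences.

Empirical tail probabilities against the replicate null use the raw
counting estimator `#{null >= obs}/n_sim` with ties counted in both
tails (so `p_lower + p_upper = 1 + ties/n_sim` exactly); the
bias-corrected `(k+1)/(n+1)` variant is selectable. Classification at
`alpha_per_tail = 0.025` (closed tails): extreme upper/lower slope ->
positive/negative directional selection; extreme upper cumulative change
-> fluctuating selection; extreme lower -> balancing selection holding
the frequency near an equilibrium; co-occurring labels are all reported,
none at all -> consistent with drift. Tails of exactly zero are rendered
`< 1/n_sim` in text output and stored as 0.

## Reproducibility and numerics

One root seed per run. Replicate `r` consumes a child stream spawned
from `SeedSequence(seed)`, and the engine draws exactly two uniforms per
individual per replicate whether or not both are used; the vectorised
multi-replicate path and the scalar single-drop path are therefore
bit-identical given the same stream, and results are invariant to how
replicates are batched. Frequency-table rows are exact count ratios and
sum to 1 to 1e-12. Contrast flagging uses an absolute guard of 1e-12
when testing credible-interval exclusion of zero, absorbing float
residue in the degenerate all-equal case.

## Association post-processing

Fitness models are typically fitted externally as Bayesian animal models
(pedigree-relatedness random effect); this package deliberately does not
re-implement that machinery. It consumes posterior draws (or a
mean/covariance summary) and computes:

* Wald test `W = b' V^{-1} b` over the K-1 haplotype-dosage coefficients
  (reference haplotype omitted from the design, so df = K-1 = 7 for
  eight haplotypes), p from the upper chi-square tail. Singular
  sub-covariances fall back to a pseudo-inverse with a logged warning.
* Haplotype-vs-rest contrasts `c_i = b_i - mean_{j!=i}(b_j)` per draw,
  with the reference effect fixed at 0 and included in the means;
  flagged when the equal-tailed 95% interval excludes zero. Contrasts
  are invariant to the choice of reference (verified in tests). The
  sequential convention — interpret contrasts only after a significant
  Wald test — is the caller's responsibility; the CLI prints a caution.

`fit_glm` is a maximum-likelihood *fixed-effects* fitter for the same
error families (probit, log-Poisson, zero-inflated Poisson with a
shared logit inflation intercept, ordinal probit), used to validate the
machinery on synthetic data. At zero inflation weight fixed to 0 the
zero-inflated model is the plain Poisson and is fitted as such. The
ordinal family takes no intercept column (thresholds absorb it).

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:
overlapping generations, ~24 annual birth cohorts, polygyny, small
litters, incomplete genotyping. Defaults (chosen once as realistic
study-like values):

| parameter | default | meaning |
|---|---|---|
| `n_founders` | 100 | founders, birth years 1985–1988 |
| `cohort_years` | 1989–2012 | 24 study cohorts |
| `founder_hap_freqs` | 8 haplotypes, D = 0.03 | one rare haplotype |
| `juvenile_survival` | 0.45 | first-year survival baseline |
| `adult_survival_young/old` | 0.75 / 0.60 (age 7+) | annual adult survival |
| `litter_probs` | (0.15, 0.55, 0.28, 0.02) | litter of 0–3 per female-year |
| `male_skew` | 0.7 | gamma shape of male siring weights |
| `genotyping_missingness` | 0.15 | diplotypes hidden at random |

These produce ~1300 individuals with a stable standing population of a
few hundred, male annual breeding success ranging from 0 to the
mid-twenties, and females capped at 3 — the sex-specific fitness
distributions the error families above expect. Selection enters as
multiplicative factors per carried copy on juvenile survival probability
(clamped to [0, 1]) and on male siring weight; this is a convenient,
documented mechanism for power experiments, not a claim about the real
one. Fitness records follow the six standard definitions (total fitness
over all born; juvenile survival; adult annual survival; adult lifespan;
adult annual and lifetime breeding success), with individuals alive at
the study end censored there.

What the generator does *not* emulate: density dependence and population
crashes, spatial structure, inbreeding depression, age-structured
fertility, immigration, genotyping error (as opposed to missingness).
Passing tests on this generator therefore show the machinery is correct
under the stated model, not that real data meet its assumptions.

## Validation experiments and problem sizes

The acceptance-level tests (`tests/test_acceptance.py`) and the
recomputation script (`scripts/acceptance.py`) run, at sizes chosen to
make Monte-Carlo error small relative to the tolerances:

* **Mendelian oracle**: on small (<= 12 individual) pedigrees mixing
  observed founders, half-known parents and cohort sampling, simulated
  diplotype distributions at 10^4 replicates match exhaustive
  enumeration of the transmission tree within 3 SE per category.
* **Expectation conservation**: 2000 neutral replicates on a synthetic
  population; per-haplotype replicate-mean final-year frequency within
  3 SE of the exact propagated expectation.
* **Type-I error**: 400 neutral populations (two 200-population seed
  batches; ~1500 individuals, 20 cohorts each), gene-drop test at
  n_sim = 500; per-tail slope rejection counts inside the exact binomial
  99% interval around 0.025, plus approximate uniformity of the
  upper-tail p-values (KS < 0.1). Calibration here is not an
  approximation: under neutrality the observed trajectory is
  exchangeable with the simulated replicates conditional on the pedigree
  and founder genotypes.
* **Power**: juvenile-viability selection s = 0.5 on a haplotype founded
  at frequency 0.05 is flagged directionally positive in well over half
  of 100 replicate populations (observed ~0.8–0.9).
* **GLM recovery**: 100 fits per family at n = 2000; all generating
  coefficients within 3 SE in >= 95% of fits.

`scripts/acceptance.py` re-runs scaled versions of these (100
populations for type-I, 50 for power, 40 fits per family) plus the exact
toy statistics, from a single command-line seed.

## Known limitations

* The standing population is reconstructed from birth/death intervals;
  a field census could differ for animals with unknown fates.
* The gene-drop conditions on observed cohort frequencies held fixed
  across replicates; re-estimating them per replicate would propagate
  their sampling noise instead.
* The empirical p-value resolution is 1/n_sim; with the default 5000
  replicates, reported zeros mean "< 0.0002".
* `fit_glm` ignores relatedness; on pedigreed data its standard errors
  are anti-conservative, which is why real analyses should feed external
  mixed-model posteriors into the Wald/contrast layer instead.
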