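# Methods

## The supra-multiplicativity test (SMT)

`supramult` tests whether the joint disease risk of a pre-specified set of
n SNPs (2 ≤ n ≤ 500) deviates from the multiplicative prediction of their
marginal effects. On the logistic scale multiplicative relative risks are
additive, so "supra-multiplicativity" means a positive departure from
additivity in

    logit P(case | x) = μ + Σᵢ βᵢ xᵢ ,

where xᵢ ∈ {0, 1, 2} counts the *externally designated* risk allele of SNP
i (dosages in [0, 2] are accepted). Writing L = Σᵢ wᵢ xᵢ for the
(optionally weighted) risk-allele load, the alternative model adds a single
indicator:

    logit P(case | x) = μ + Σᵢ βᵢ xᵢ + π · 1{L ≥ T} .

For every *valid* cut-off T — a value with individuals on both sides of the
split — the indicator is tested with one degree of freedom, and the scan is
Bonferroni-corrected over the v valid cut-offs:

    p_final = min(1, v · min_T p_T) .

Because the per-threshold statistics are positively dependent, the
correction is conservative; the package's own level study reproduces the
mild conservativeness (empirical level ≈ 0.042–0.045 at nominal 0.05).

Design choices:

* **Inference.** The per-threshold p-value is a likelihood-ratio test by
  default (`inference="lrt"`); Wald p-values and the Wald effect estimate
  π̂ with its standard error are available because the threshold profile
  reports them. The LRT is better calibrated at small α and does not
  suffer the Hauck–Donner collapse for large indicator effects.
* **Threshold grid.** Valid thresholds are the distinct observed load
  values excluding the minimum, so each distinct above/below split is
  tested exactly once. With unit weights and a densely observed integer
  load range this equals {min(L)+1, …, max(L)}; with real-valued
  (weighted) loads it generalises without change.
* **Separation.** A threshold whose indicator separates the data (fitted
  probabilities saturated beyond 1e−6 together with a diverging
  coefficient, e.g. an above-threshold group containing only cases) has an
  unbounded coefficient MLE but a finite likelihood supremum. The scan
  therefore keeps the likelihood-ratio p-value — one degenerate cut-off
  must not kill a 500-SNP scan, and discarding the evidence there makes
  the corrected test visibly over-conservative under the null — while
  flagging the row and reporting an infinite standard error, so the effect
  estimate never enters diagnostics and Wald inference substitutes p = 1.
* **Orientation is external.** Loads are computed from a risk-allele
  specification file, never from the analysed sample's own effect
  directions; `io.draft_risk_spec_from_data` exists for exploration but
  marks its output `data_derived`.
* **Ties and determinism.** The best threshold is the smallest T among
  equal minimal p-values; given identical inputs and seeds all outputs are
  bit-identical.
* **Missing data.** The load needs every SNP, so individuals with any
  missing genotype are excluded at read time (counts logged). Imputed
  dosages can be used instead; the threshold grid then runs over observed
  load values.

The threshold profile doubles as a diagnostic: under a limiting-pathway
model π̂_T rises to a sharp maximum at the generating threshold (see
"Threshold recovery" below). Alongside π̂ the profile reports the plain
2×2 above/below-threshold odds ratio with the standard error of its log
(Haldane–Anscombe 0.5 correction on empty cells, flagged).

## Adjusted SMT

Known dominance deviations or low-order interactions inflate the plain
SMT level (they are themselves deviations from multiplicativity). They can
be absorbed by adding covariates to both models: heterozygote indicators
for dominance, and pair/triple product terms for interactions. Pair
adjustment defaults to "genotypic" — the pair members' dominance terms plus
all four {additive, dominance}² products — because that block spans the
full 3×3 genotype table of the pair; a double-recessive pair effect lies
outside the span of the single allelic product, and only the full span
restores the nominal level. Saturated pair adjustments can lose rank when
a rare genotype cell is empty; dependent adjustment columns are then
dropped (the corresponding cells carry no individuals, so nothing real is
adjusted away).

## Comparator tests

* single-marker: 1-d.f. additive logistic LRT, reporting the allelic OR;
* dominance: 1-d.f. heterozygote-indicator LRT on top of the additive term;
* pairwise interaction: LRT of the product block over the main effects —
  allelic mode (1 d.f., product of additive terms over additive mains) or
  genotypic mode (4 d.f., {additive, dominance}² products over
  additive + dominance mains);
* three-way interaction: LRT of the triple block (1 or 8 d.f.) over all
  main effects and all two-way products of the chosen mode.

Sparse tables empty genotype cells long before asymptotics fail; linearly
dependent interaction terms are dropped with the degrees of freedom
reduced and the result flagged, and a fully collapsed block returns the
conservative p = 1 rather than an error. `best_of_set` enumerates all
singles/pairs/triples of a set and applies either the
most-significant-member policy (no correction) or the α/m Bonferroni
policy.

## Synthetic data: what the generator emulates

All test and acceptance inputs come from `supramult.simulate`; no external
cohort is shipped or required. Genotypes are independent Hardy–Weinberg
draws (counts ~ Binomial(2, qᵢ)), i.e. no LD beyond the explicit
single-proxy tagging, no population structure, no genotyping error, and
case-control sampling is exact-quota rejection sampling from the
penetrance model. Real GWAS data violate all of these in some measure, so
passing tests demonstrate correctness of the statistics under the stated
models, not robustness to cohort artefacts.

Penetrance models and their defaults:

* **Multiplicative null** — per-SNP risk-allele frequencies uniform on
  (0.1, 0.9) and per-allele relative risks uniform on [1.2, 1.5], both
  redrawn every replicate; baseline calibrated to a population prevalence
  of 0.05. The relative risks combine on the *odds* scale by default
  (`scale="odds"`: logit-linear, the exact null of the logistic tests).
  `scale="risk"` implements literal risk-scale multiplication with the
  penetrance capped at 1; the two coincide only for rare outcomes, and at
  prevalence ≈ 5% the risk scale is measurably supra-multiplicative on the
  logit scale in its upper load tail (the level of the SMT under it is
  ≈ 0.13 at nominal 0.05 — useful as a sensitivity scenario, not as a
  null). A risk-scale model whose cap bites for more than 0.1% of the
  population is rejected as misconfigured.
* **Semi-null B1 / B2** — 30 SNPs by default; B1 makes 15 SNPs purely
  recessive with a required homozygote relative risk, B2 gives 7 disjoint
  SNP pairs a required double-recessive relative risk; remaining SNPs act
  per-allele as in the null. Effect sizes have *no default* (the source
  study does not print them); callers must choose them, and the package's
  qualitative level checks state their choices explicitly (hom_rr = 2,
  pair_rr = 4).
* **LPLM** — limiting-pathway liability model: penetrance f0 = 0.03 below
  and p1 above a load threshold T*, with T* calibrated by exact
  dynamic-programming convolution of the per-SNP count distributions so
  that ≈ 1.5% of the population lies at or above T* (the achieved tail is
  reported; small sets cannot hit 1.5% exactly). Per-SNP frequencies
  default to 0.5 (symmetric exchangeable model) because the source's
  frequencies are not recoverable; p1 is the caller's choice from the
  grid 0.1/0.3/0.5/0.7 used in the power study. The weighted variant
  keeps T* and weights the load contributions 0.5/1/2 in thirds of the
  set order.
* **Recessive REZ-A…D** — 3 SNPs, baseline 0.03, elevated penetrance only
  for the triple homozygous-risk genotype; presets carry the published
  frequency/penetrance quadruples (A: 0.2/0.5/0.8 with 0.20; B:
  0.2/0.3/0.4 with 0.70; C: 0.4/0.5/0.6 with 0.10; D: 0.6/0.7/0.8 with
  0.05). Exact HWE enumeration of the implied marginal allelic relative
  risks reproduces the published ranges (e.g. 1.03–1.07 for REZ-B).

LD tagging replaces each causal SNP by a proxy drawn from a two-locus
haplotype model with allele correlation √r² (default: proxy frequency
equal to the causal frequency, r² = 0.8 in the study design); infeasible
frequency/r² combinations are rejected with the attainable bound.

Sample sizes default to 3,000 cases and 3,000 controls, and study runs to
1,000 replicates, matching the study design the package reproduces. Tests
and examples use smaller replicate counts chosen so the binomial
Monte-Carlo error (always reported alongside each proportion) stays small
relative to the property being checked.

## Numerical choices

* IRLS/Newton with step halving; convergence when the relative
  log-likelihood change falls below 1e−10 (max 100 iterations). The
  threshold scan warm-starts every alternative fit from the null fit.
* X᙮WX is accumulated with a symmetric rank-k BLAS update and factorised
  by Cholesky; a singular factorisation triggers pivoted-QR diagnosis and
  a `CollinearityError` naming the dependent columns.
* Log-likelihoods use `logaddexp`; weights are floored at 1e−12.
* Column-independence decisions (interaction-block collapse, adjustment
  pruning) use greedy Gram–Schmidt with a 1e−8 relative residual
  tolerance.
* The load-distribution convolution rounds support values to 9 decimals
  to merge floating-point duplicates of weighted loads.
* Odds-scale model prevalence without a calibration hint is evaluated by
  a fixed-seed 100,000-draw Monte Carlo (documented as such); risk-scale,
  LPLM and recessive prevalences are exact.
* Seeding: a study's master seed spawns one `SeedSequence` child per
  replicate, so any replicate is reproducible in isolation and results do
  not depend on loop scheduling.

## Threshold recovery

On self-generated 30-SNP LPLM data (p1 = 0.5, 3,000/3,000) the profile
peak `ThresholdProfile.peak_threshold()` equals the generating T* in ≳ 90%
of runs when the causal SNPs are analysed directly. Under r² = 0.8 tagging
the peak lands close to but systematically 1–2 units *above* T*: with
imperfect proxies, P(elevated risk | proxy load ≥ T) keeps increasing
beyond T*, so the adjusted indicator estimate continues to rise past the
true threshold before small-group noise takes over. The acceptance suite
asserts the ±1 property as specified for the study design and documents
this bias where it fails.

## Known limitations

* At separated thresholds the chi-square calibration of the supremum LRT
  rests on the same asymptotics as elsewhere but with one sparse cell;
  the level study shows the scan stays (mildly) conservative overall, but
  per-threshold p-values at near-empty splits should be read with care.
* Bonferroni over the threshold scan is the only multiplicity correction;
  no permutation alternative is implemented.
* Binary phenotypes only; no quantitative-trait version, no Firth
  penalisation, no haplotype-based loads, no genome-wide subset search.
* The simulator's LD model is single-proxy tagging; it does not emulate
  haplotype-block structure.
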