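# supramult

A one-degree-of-freedom **supra-multiplicativity test (SMT)** for
pre-specified SNP sets in case-control data, together with the standard
comparator tests (single-marker, dominance, 2-/3-SNP interaction) and a
penetrance-model simulator for level and power studies.

## The problem

Genome-wide association studies explain only part of complex-disease
heritability, and pairwise SNP-SNP interaction scans have found little.
One proposed explanation is limiting-pathway liability architecture: risk
is roughly constant until an individual's count of risk alleles crosses a
critical threshold, after which it jumps. Such models imply interactions
of *every* order, each individually tiny — invisible to 2-SNP tests at
realistic sample sizes. The SMT targets exactly this signature with a
single parameter.

For a set of n SNPs (2 ≤ n ≤ 500) with externally designated risk alleles,
let xᵢⱼ count risk alleles of SNP i in individual j and
L⁽ʲ⁾ = Σᵢ wᵢ xᵢⱼ be the (optionally weighted) risk-allele load. For each
load cut-off T the SMT compares

    H₀:  logit P(case) = μ + Σᵢ βᵢ xᵢ
    H₁:  logit P(case) = μ + Σᵢ βᵢ xᵢ + π · 1{L ≥ T}

with a 1-d.f. likelihood-ratio test of π. All v valid cut-offs (those with
individuals on both sides) are scanned and Bonferroni-corrected:
**p_final = min(1, v · min_T p_T)**. A positive π̂ at high T means the
joint risk of many risk alleles exceeds the multiplicative prediction of
their marginal effects. Further covariates — including known dominance or
interaction terms that should be adjusted away — enter both models.

Intended users: statistical geneticists screening confirmed susceptibility
SNP sets (a GWAS-catalogue gene set, a pathway panel) for joint effects
beyond multiplicativity, and methodologists studying threshold
architectures in simulation.

## Worked example

Simulate a 3-SNP completely recessive scenario (risk-allele frequencies
0.2/0.5/0.8; penetrance 0.20 for the triple homozygous-risk genotype,
0.03 otherwise; 3,000 cases and 3,000 controls) and scan the load
thresholds:

```python
from supramult.simulate import RecessiveModel, sample_case_control
from supramult.smt import smt_test

rep = sample_case_control(RecessiveModel.rez_a(), 3000, 3000, seed=1)
res = smt_test(rep.genotypes, rep.phenotype, rep.spec)
print(res.profile.data)
print(res.v, res.best_threshold, res.p_final)
```

Output (`python examples/run_smt_on_recessive_data.py`):

```
 threshold   p_value      pi   se_pi  odds_ratio  se_log_or  freq_cases  freq_controls
         1    0.6695 -0.1344  0.3147           1     0.3026      0.9927         0.9927
         2   0.02743 -0.2691  0.1221      0.9371        0.1       0.926         0.9303
         3   0.02653 -0.2014 0.09082       1.044    0.05557      0.6893           0.68
         4   0.06644 -0.1711 0.09323       1.089    0.05509      0.3357          0.317
         5   0.05624  0.2278  0.1195        1.41    0.09055      0.1057        0.07733
         6 1.948e-24   2.636  0.3413       12.89     0.3298     0.04133       0.003333

valid thresholds v = 6
best threshold     = 6
corrected p_final  = 1.169e-23
```

Each row is one cut-off T: the uncorrected 1-d.f. p-value, the indicator
estimate π̂ with its standard error, the plain 2×2 above/below-threshold
odds ratio with se(log OR), and the fraction of cases/controls at or above
T. The risk jump sits at the maximum load 6 (all three SNPs homozygous):
π̂ leaps to 2.6 there, 4.1% of cases but only 0.3% of controls are above,
and the Bonferroni-corrected p-value (6 × min p) is ≈ 1e−23 — the
threshold architecture is detected although no single marker or SNP pair
carries strong evidence.

Other entry points, each demonstrated by a script in `examples/`:

* `threshold_profile` / `ThresholdProfile.peak_threshold` — liability-
  threshold recovery diagnostics, with `make_tagged_proxies` for
  imperfect-tagging scenarios;
* `adjusted_smt` — covariate adjustment for known dominance/interaction
  terms;
* `comparators.best_of_set` — most-significant single/pair/triple
  screening with optional α/m correction;
* `study.run_level_study` / `run_power_study` / `run_subset_curve` —
  replicated Monte-Carlo studies with per-replicate reproducible seeding;
* a thin command line: `smt {run,screen,simulate,level,power,curve}`
  over VCF / dosage-TSV / phenotype-TSV / risk-allele-spec files.

See `docs/methods.md` for the model, the simulator's assumptions, and the
numerical policies (threshold grid, separation handling, calibration).

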