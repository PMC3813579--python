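"""Empirical level of the SMT under a multiplicative null model.

Each replicate draws fresh allele frequencies (uniform on 0.1-0.9) and
per-allele relative risks (uniform on 1.2-1.5), combines them with no
interaction on the logit scale, samples 3,000 cases and 3,000 controls,
and applies the Bonferroni-corrected SMT.  A small run (100 replicates,
10 SNPs) keeps this quick; the published study used 1,000 replicates.
"""

from supramult.simulate import MultiplicativeModel
from supramult.study import StudyConfig, run_level_study

cfg = StudyConfig(
    model=lambda rng: MultiplicativeModel.draw_null(10, rng),
    n_replicates=100, alphas=(0.05, 0.005), tests=("smt",), seed=7,
)
res = run_level_study(cfg)
print(res.summary.to_string(index=False))
print()
print(
    "The rejection proportion at each nominal level estimates the type-I\n"
    "error; 'se' is its binomial Monte-Carlo error.  Because the per-\n"
    "threshold tests are positively dependent, the Bonferroni correction\n"
    "makes the test slightly conservative (empirical level a bit below\n"
    "nominal)."
)
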