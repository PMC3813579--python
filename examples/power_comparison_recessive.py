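"""SMT versus standard interaction tests under a 3-SNP recessive model.

Under REZ-C (frequencies 0.4/0.5/0.6, triple-homozygote penetrance 0.10)
the high-risk genotype spreads its signal over dominance and interaction
terms of every order, so single-marker and interaction tests struggle at
stringent significance levels while the 1-d.f. SMT remains powerful.
A 150-replicate run keeps this demo quick.
"""

from supramult.simulate import RecessiveModel
from supramult.study import StudyConfig, run_power_study

cfg = StudyConfig(
    model=RecessiveModel.rez_c(),
    n_replicates=150,
    alphas=(5e-2, 5e-4, 5e-8),
    tests=("smt", "single_marker_best", "pairwise_1df_best", "threeway_1df"),
    seed=17,
)
res = run_power_study(cfg)
print(res.summary.to_string(index=False))
print()
print(
    "At the genome-wide level 5e-8 the comparators' power collapses while\n"
    "the SMT retains most of its power: the load-threshold indicator pools\n"
    "the two- and three-way interaction evidence into one degree of freedom."
)
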