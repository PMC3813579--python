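"""Adjusting the SMT for known low-order interactions.

Simulates a semi-null model in which 7 SNP pairs act double-recessively
(relative risk 4 for the 4-risk-allele two-locus genotype) on top of a
multiplicative base.  The plain SMT picks this two-way signal up; adding
the pair covariates to both models removes it, so the adjusted test asks
for supra-multiplicativity beyond the known interactions.
"""

import numpy as np

from supramult.simulate import PairwiseSemiNullModel, sample_case_control
from supramult.smt import adjusted_smt, smt_test

rng = np.random.default_rng(3)
model = PairwiseSemiNullModel.draw(rng, pair_rr=4.0)
rep = sample_case_control(model, 3000, 3000, rng)

plain = smt_test(rep.genotypes, rep.phenotype, rep.spec)
ids = rep.genotypes.snp_ids
pairs = [(ids[a], ids[b]) for a, b in model.pairs]
adj = adjusted_smt(rep.genotypes, rep.phenotype, rep.spec, interaction_pairs=pairs)

print(f"plain SMT:    p_final = {plain.p_final:.4f} (best T = {plain.best_threshold:g})")
print(f"adjusted SMT: p_final = {adj.p_final:.4f} (best T = {adj.best_threshold:g})")
print()
print(
    "Across replicates of this model the plain SMT rejects at ~2x the\n"
    "nominal rate, while the pair-adjusted SMT is calibrated: a significant\n"
    "adjusted result would indicate interaction beyond the known pairs."
)
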