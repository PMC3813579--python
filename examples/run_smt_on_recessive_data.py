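"""Run the supra-multiplicativity test on one simulated recessive dataset.

Simulates the REZ-A scenario (3 SNPs, risk-allele frequencies 0.2/0.5/0.8,
baseline penetrance 0.03, penetrance 0.20 for the triple homozygous-risk
genotype; 3,000 cases and 3,000 controls) and scans all valid allele-load
cut-offs.
"""

from supramult.simulate import RecessiveModel, sample_case_control
from supramult.smt import smt_test

rep = sample_case_control(RecessiveModel.rez_a(), 3000, 3000, seed=1)
res = smt_test(rep.genotypes, rep.phenotype, rep.spec)

print(res.profile.data.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print(f"valid thresholds v = {res.v}")
print(f"best threshold     = {res.best_threshold:g}")
print(f"corrected p_final  = {res.p_final:.3e}")
print()
print(
    "The per-threshold rows mirror the published layout: indicator estimate\n"
    "pi with its s.e., the 2x2 above/below-threshold odds ratio, and the\n"
    "fraction of cases/controls above each cut-off.  The top threshold (all\n"
    "six risk alleles) isolates the high-risk genotype, so pi jumps there and\n"
    "the Bonferroni-corrected p remains far below 0.05."
)
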