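"""Recover a liability threshold from the pi-hat profile.

Simulates a 30-SNP limiting-pathway liability model whose threshold T* is
calibrated so ~1.5% of the population carries a risk-allele load >= T*,
then shows that the indicator-effect profile peaks at T* when the causal
SNPs are observed directly, and nearby when only r^2 = 0.8 proxies are.
"""

from supramult.simulate import LplmModel, make_tagged_proxies, sample_case_control
from supramult.smt import RiskAlleleSpec, threshold_profile

model = LplmModel.calibrated(30, p1=0.5)
print(f"calibrated threshold T* = {model.threshold:g} "
      f"(population tail {model.population_tail():.3%})")

rep = sample_case_control(model, 3000, 3000, seed=5)
prof = threshold_profile(rep.genotypes, rep.phenotype, rep.spec)
print(f"perfect tagging: pi-hat profile peaks at T = {prof.peak_threshold():g}")

proxies = make_tagged_proxies(rep.genotypes, model.q, 0.8, seed=6)
spec = RiskAlleleSpec.from_lists(proxies.snp_ids, rep.spec.risk_alleles)
tagged = threshold_profile(proxies, rep.phenotype, spec)
print(f"r^2=0.8 tagging: profile peaks at T = {tagged.peak_threshold():g}")
print()
print(
    "With the causal SNPs in hand the peak coincides with the simulated\n"
    "threshold; with imperfect proxies the profile flattens and the peak\n"
    "lands close to (typically just above) the true T*."
)
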