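"""Power of the SMT when only part of a liability pathway is known.

Data are generated under a full 20-SNP limiting-pathway liability model,
but the SMT only sees the first k SNPs, mimicking incomplete knowledge of
the pathway.  A small run (60 replicates) sketches the power-vs-k curve;
power rises steeply once a sufficient fraction of the model SNPs is
available.
"""

from supramult.simulate import LplmModel
from supramult.study import StudyConfig, run_subset_curve

model = LplmModel.calibrated(20, p1=0.7)
cfg = StudyConfig(
    model=model, n_replicates=60, alphas=(1e-4,),
    subset_sizes=(4, 8, 12, 16, 20), seed=23,
)
res = run_subset_curve(cfg)
print(res.summary[["subset_k", "alpha", "power", "se", "reps"]]
      .to_string(index=False))
print()
print(
    "Each row is the SMT rejection proportion when only the first k of the\n"
    "20 model SNPs are analysed (data always generated under the full\n"
    "model).  Power is negligible for small subsets and saturates well\n"
    "before the full set is available."
)
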