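import numpy as np
import pytest

from supramult.simulate import RecessiveModel, sample_case_control
from supramult.smt import GenotypeMatrix, RiskAlleleSpec


@pytest.fixture(scope="session")
def rez_a_replicate():
    """One REZ-A case-control replicate (3-SNP recessive model)."""
    return sample_case_control(RecessiveModel.rez_a(), 1500, 1500, seed=11)


@pytest.fixture()
def small_logistic_data():
    """20-row, 2-covariate dataset with a fixed seed for oracle comparisons."""
    rng = np.random.default_rng(7)
    x1 = rng.normal(size=20)
    x2 = rng.integers(0, 3, size=20).astype(float)
    eta = -0.3 + 0.8 * x1 + 0.4 * x2
    y = (rng.random(20) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.min() == y.max():  # pragma: no cover - seed chosen to avoid this
        y[0] = 1 - y[0]
    return x1, x2, y


@pytest.fixture()
def toy_genotypes():
    """Deterministic 6-individual x 3-SNP matrix with allele labels."""
    values = np.array(
        [
            [0, 1, 2],
            [1, 1, 1],
            [2, 0, 0],
            [2, 2, 2],
            [0, 0, 1],
            [1, 2, 0],
        ],
        dtype=float,
    )
    G = GenotypeMatrix(
        values=values,
        snp_ids=("rs1", "rs2", "rs3"),
        sample_ids=tuple(f"s{i}" for i in range(6)),
        counted_alleles=(("A", "G"), ("C", "T"), ("G", "A")),
        oriented=False,
    )
    spec = RiskAlleleSpec.from_lists(["rs1", "rs2", "rs3"], ["A", "T", "G"])
    return G, spec
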