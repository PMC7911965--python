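import numpy as np
import pytest
from hypothesis import settings

from epimoga import GenotypeDataset, build_dme_model, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_dataset() -> GenotypeDataset:
    """Six samples x three SNPs, no missing data, both classes present."""
    genotypes = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 0, 0],
            [1, 2, 2],
            [2, 2, 1],
        ],
        dtype=np.int8,
    )
    phenotype = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
    return GenotypeDataset(genotypes, phenotype, ["rs1", "rs2", "rs3"])


@pytest.fixture(scope="session")
def dme2_dataset():
    """One strong threshold-model dataset (MAF 0.1, h2 0.05, 400/400, 100 SNPs)."""
    model = build_dme_model("DME2", maf=0.1, h2=0.05, prevalence=0.2)
    rng = np.random.Generator(np.random.PCG64(20240817))
    ds, truth = simulate_dataset(model, 400, 400, 100, rng)
    return ds, truth


def make_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))
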