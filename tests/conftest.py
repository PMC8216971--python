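import numpy as np
import pytest

from provscan.core_io import GenotypeDataset, LocusInfo
from provscan.simulate import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def default_sim():
    """Default recovery scenario: 16 demes, ~170 samples, planted adaptive loci."""
    cfg = SimConfig(seed=123)
    ds, truth = simulate_genotypes(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def neutral_sim():
    """Neutral scenario matched to the null model's parameterization."""
    cfg = SimConfig(n_adaptive_loci=0, F_CT=0.05, F_SC=0.05, seed=321)
    ds, truth = simulate_genotypes(cfg)
    return cfg, ds, truth


@pytest.fixture
def tiny_ds():
    """Hand-built 4-sample x 3-locus dataset."""
    loci = [
        LocusInfo("l1", "s1", 100, "A", "C"),
        LocusInfo("l2", "s1", 200, "G", "T"),
        LocusInfo("l3", "s2", 50, "A", "G"),
    ]
    dosage = np.array(
        [
            [0, 1, 2],
            [1, 2, -1],
            [2, 0, 0],
            [0, 1, 1],
        ],
        dtype=np.int16,
    )
    prov = {"a_1": "a", "a_2": "a", "b_1": "b", "b_2": "b"}
    return GenotypeDataset(["a_1", "a_2", "b_1", "b_2"], loci, dosage, prov)
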