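import numpy as np
import pandas as pd
import pytest

from clockshift import MethylationDataset, SimulationConfig, simulate_aging_methylation


@pytest.fixture
def tiny_dataset():
    """2 samples × 2 CpGs with ages, for round-trip and bounds tests."""
    beta = pd.DataFrame(
        [[0.125, 0.875], [0.333333333333333, 0.5]],
        index=["s1", "s2"],
        columns=["cg000001", "cg000002"],
    )
    age = pd.Series([30.0, 60.0], index=["s1", "s2"])
    return MethylationDataset(beta=beta, age=age)


@pytest.fixture(scope="session")
def aging_dataset():
    """Default synthetic aging cohort (200 × 500, 50 age-linked CpGs)."""
    return simulate_aging_methylation(SimulationConfig(seed=7))


def make_noiseless_linear(n_samples=30, n_decoys=0, slope=0.005, intercept=0.3,
                          age_lo=20.0, age_hi=80.0, seed=0):
    """One CpG exactly linear in age (no noise) plus optional constant decoys."""
    rng = np.random.default_rng(seed)
    ages = np.linspace(age_lo, age_hi, n_samples)
    data = {"cg_linear": intercept + slope * ages}
    for i in range(n_decoys):
        data[f"cg_decoy{i:03d}"] = np.full(n_samples, rng.uniform(0.2, 0.8))
    beta = pd.DataFrame(data, index=[f"s{i:03d}" for i in range(n_samples)])
    age = pd.Series(ages, index=beta.index)
    return MethylationDataset(beta=beta, age=age)
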