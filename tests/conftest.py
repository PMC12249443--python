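import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ssgblup import SimulationConfig, simulate_herd
from ssgblup.simulate import SyntheticTraitDefinition


@pytest.fixture(scope="session")
def small_herd():
    """Shared small herd: ~360 animals, 2 generations, 30% genotyped."""
    cfg = SimulationConfig(
        n_founders=120, n_generations=2, dams_per_sire=3, offspring_per_dam=2,
        n_snps=200, genotyping_fraction=0.3, seed=42,
    )
    traits = [
        SyntheticTraitDefinition("yield", mean=10.0, h2_true=0.3, repeatability=0.45,
                                 residual_sd=1.0, records_per_animal=2, group="milk"),
        SyntheticTraitDefinition("gain", mean=2.0, h2_true=0.35, residual_sd=0.8,
                                 group="growth_6mo",
                                 genetic_correlation_partner=("size", 0.5)),
        SyntheticTraitDefinition("size", mean=1.0, h2_true=0.4, residual_sd=0.5,
                                 group="growth_6mo"),
    ]
    return simulate_herd(cfg, traits)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
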