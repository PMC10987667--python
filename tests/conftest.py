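from __future__ import annotations

import numpy as np
import pytest

from phoswave.synthetic_data import SimConfig, SyntheticDataset, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced experiment for unit tests: same structure, fewer features."""
    return SimConfig(n_proteins=80, n_sites=220, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SyntheticDataset:
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def noiseless_dataset() -> SyntheticDataset:
    """No noise, no dropout, unit channel/batch factors: planted signal only."""
    cfg = SimConfig(
        n_proteins=60, n_sites=150, seed=11,
        noise_cv=0.0, channel_scale_sd_log2=0.0, batch_effect_sd_log2=0.0,
        dropout_slope=60.0, dropout_midpoint_log10=-10.0,  # P(zero) ~ 0
        fraction_reverse=0.0, fraction_contaminant=0.0,
        loc_pass_fraction=1.0,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
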