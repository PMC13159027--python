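"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from stimrel.synthetic import (
    SyntheticConfig,
    generate_ephys_cohort,
    generate_hemo_cohort,
    generate_latent_stimulus,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale cohort: 6 subjects, 32 grid channels, 2 bands, 297 s."""
    return SyntheticConfig(
        n_subjects_ephys=6,
        n_subjects_hemo=4,
        n_electrodes=40,
        grid_shape=(4, 4, 2),
        bands=("theta", "hf"),
        band_coupling_signs={"theta": -1, "hf": 1},
        shared_frac=0.1,
        subject_frac=0.1,
        seed=12345,
    )


@pytest.fixture(scope="session")
def latent(small_config):
    return generate_latent_stimulus(small_config)


@pytest.fixture(scope="session")
def ephys_cohort(latent, small_config):
    return generate_ephys_cohort(latent, small_config)


@pytest.fixture(scope="session")
def hemo_cohort(latent, small_config):
    return generate_hemo_cohort(latent, small_config)


@pytest.fixture(scope="session")
def ephys_envelopes(ephys_cohort):
    return ephys_cohort.to_envelope_set()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987)
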