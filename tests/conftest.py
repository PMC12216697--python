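import numpy as np
import pytest

from soundlur import synthetic_city as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.CityConfig(
        extent_m=(2000.0, 2000.0),
        n_fixed_sites=3,
        n_rotating_sites=24,
        campaign_days_fixed=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_rasters(small_config):
    return syn.generate_covariate_rasters(small_config)


@pytest.fixture(scope="session")
def small_vectors(small_config, small_rasters):
    return syn.generate_vector_layers(small_config, small_rasters)


@pytest.fixture(scope="session")
def small_sites(small_config, small_rasters):
    return syn.sample_sites(small_config, small_rasters)


@pytest.fixture(scope="session")
def ground_truth():
    return syn.default_ground_truth()


@pytest.fixture(scope="session")
def small_clips(small_sites, ground_truth, small_rasters, small_vectors, small_config):
    return syn.simulate_clip_labels(
        small_sites, ground_truth, small_rasters, small_vectors, small_config
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
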