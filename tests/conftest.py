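import logging

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aprmap.domain import load_crop_class_map, load_regions, load_taxonomy
from aprmap.pipeline import run_synthetic
from aprmap.synthetic import SyntheticScenario

# the EXCLUDED-code warning fires for every synthetic raster; keep test
# output readable
logging.getLogger("aprmap.domain").setLevel(logging.ERROR)
logging.getLogger("aprmap.model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def class_map():
    return load_crop_class_map()


@pytest.fixture(scope="session")
def regions():
    return load_regions()


@pytest.fixture(scope="session")
def small_zero_noise_run():
    """End-to-end run of the four-country fixture with exact (noise-free,
    dense) reference data: the calibration optimum reproduces the truth."""
    scenario = SyntheticScenario.small(seed=11, noise_sd_log10=0.0, sparsity=0.0)
    return scenario, run_synthetic(scenario, n_realizations=400, mc_seed=11)


@pytest.fixture(scope="session")
def small_noisy_run():
    """Four-country fixture under realistic noise with some banned/missing
    structure exercised downstream."""
    scenario = SyntheticScenario.small(seed=5)
    return scenario, run_synthetic(scenario, n_realizations=400, mc_seed=5)
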