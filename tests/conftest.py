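import numpy as np
import pytest

import replichore as rp

GENOME = 4_640_000
BIN = 1000


@pytest.fixture(scope="session")
def model():
    """Bundled dual-origin E. coli model (oriC + oriZ)."""
    return rp.default_chromosome()


@pytest.fixture(scope="session")
def oriz_model(model):
    """Single ectopic-origin strain configuration (oriC deleted)."""
    return model.subset_origins(["oriZ"])


@pytest.fixture(scope="session")
def oriz_timing(oriz_model):
    return rp.simulate_replication_timing(
        oriz_model, rp.SimulationParams(doubling_time_min=39.8)
    )


@pytest.fixture(scope="session")
def oriz_copy_number(oriz_timing):
    return rp.timing_to_copy_number(oriz_timing, 39.8)


@pytest.fixture(scope="session")
def oriz_profile(oriz_copy_number):
    """Noise-free marker-frequency profile of the single-oriZ strain."""
    return rp.noise_free_profile(oriz_copy_number)


@pytest.fixture(scope="session")
def oriz_smoothed(oriz_profile):
    return rp.remove_outliers_and_refit(oriz_profile)


def circ_dist_bins(a, b, n):
    d = abs(a - b) % n
    return min(d, n - d)
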