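import numpy as np
import pytest

from flimkit.decay import IRFModel
from flimkit.simulate import (DEFAULT_FAD, DEFAULT_NADH, SimulationConfig,
                              default_config)


@pytest.fixture(scope="session")
def config():
    """Reference study conditions (64x64 images, 256 bins, 300 ps IRF)."""
    return default_config()


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled conditions for fast image-level tests."""
    return default_config(image_size=(32, 32), n_cells=3,
                          cell_radius_range=(4.0, 6.0))


@pytest.fixture(scope="session")
def irf(config):
    return config.irf


@pytest.fixture(scope="session")
def nadh():
    return DEFAULT_NADH


@pytest.fixture(scope="session")
def fad():
    return DEFAULT_FAD


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small64():
    """Twenty small 64-bin decays (12.5 ns window) with their config."""
    from flimkit.simulate import generate_decay

    cfg = default_config(n_time_bins=64, bin_width_ps=195.2,
                         irf_shift_ps=1000.0)
    rng = np.random.default_rng(2024)
    decays = []
    for i in range(20):
        day = i % 5
        total = rng.uniform(1e4, 1e5)
        hist, _ = generate_decay(DEFAULT_NADH, day, total, cfg,
                                 seed=int(rng.integers(1 << 30)))
        decays.append(hist)
    return cfg, decays
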