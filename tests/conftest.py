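import numpy as np
import pytest

from dsrt.config import DSSConfig, SimulationConfig
from dsrt.curves import fit_screen
from dsrt.dss import ScreenMatrix, score_screen
from dsrt.normalize import assemble_series, normalize_plates
from dsrt.simulate import simulate_screen


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 6 samples, 40 drugs, zero plate noise."""
    return SimulationConfig(
        n_samples_per_subtype={"HGSOC": 2, "LGSOC": 2, "MUCOC": 2},
        serial_samples=(), n_drugs=40, noise_cv=0.0, seed=7)


@pytest.fixture(scope="session")
def small_screen(small_config):
    return simulate_screen(small_config)


@pytest.fixture(scope="session")
def small_series(small_screen):
    normalized, _ = normalize_plates(small_screen.wells)
    series, _ = assemble_series(normalized)
    return series


@pytest.fixture(scope="session")
def small_matrix(small_config, small_screen, small_series):
    fits = fit_screen(small_series)
    dss_df = score_screen(fits, DSSConfig(x_min=small_config.x_min,
                                          x_max=small_config.x_max))
    return ScreenMatrix.from_long(dss_df, small_screen.samples,
                                  small_screen.library)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
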