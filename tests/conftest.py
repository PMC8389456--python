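import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """One small noisy simulated tilt series shared by detection tests."""
    from stakit.fixtures import SimulationRecipe, simulate_tilt_series

    recipe = SimulationRecipe(
        n_tilts=21, image_size=256, n_beads=8, shift_amplitude=10.0,
        snr=3.0, rng_seed=5,
    )
    return simulate_tilt_series(recipe)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free small series for exactness checks."""
    from stakit.fixtures import SimulationRecipe, simulate_tilt_series

    recipe = SimulationRecipe(
        n_tilts=21, image_size=256, n_beads=8, shift_amplitude=10.0,
        snr=np.inf, rng_seed=9,
    )
    return simulate_tilt_series(recipe)
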