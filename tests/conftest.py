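import numpy as np
import pytest

from norn import simulate


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimulationConfig:
    """Desk-scale section: 0.6 x 0.6 mm at 1 µm/px, ~25% tubule coverage."""
    return simulate.SimulationConfig(
        seed=11,
        extent=(600.0, 600.0),
        n_tubules=125,
        n_rep_cells=40,
        pixel_size=1.0,
        depth=3000.0,
        n_background_genes=60,
    )


@pytest.fixture(scope="session")
def small_sample(small_cfg):
    return simulate.simulate_sample(small_cfg)


@pytest.fixture(scope="session")
def injured_sample(small_cfg):
    return simulate.simulate_sample(small_cfg.replace(injury=True))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
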