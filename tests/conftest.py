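import numpy as np
import pytest

from standbench import SimConfig, simulate_stand


@pytest.fixture(scope="session")
def default_run():
    """Noise-free default run: P1 start, boundaries (12, 48, 130), p = -3/2."""
    cfg = SimConfig(seed=1)
    series, structure, truth = simulate_stand(cfg)
    return cfg, series, structure, truth


@pytest.fixture(scope="session")
def noisy_run():
    """Same study conditions with 2% observational noise."""
    cfg = SimConfig(seed=7, noise_sd=0.02)
    series, structure, truth = simulate_stand(cfg)
    return cfg, series, structure, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def p2_config(seed: int, **kw) -> SimConfig:
    """Immediate-seedling start without grass: open-canopy-growth first."""
    base = dict(seed=seed, initial_grass_frac=0.0, phase_boundaries=(0, 48, 130))
    base.update(kw)
    return SimConfig(**base)


def p3_config(seed: int, **kw) -> SimConfig:
    """High-density closed-canopy start: thinning from year 0."""
    base = dict(seed=seed, initial_grass_frac=0.0, phase_boundaries=(0, 0, 130),
                initial_dbh=12.0)
    base.update(kw)
    return SimConfig(**base)
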