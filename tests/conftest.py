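import numpy as np
import pytest

import sozloc as sz


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """4x4 grid, 50 Hz, one annotated seizure with no actual regime change."""
    cfg = sz.SimConfig(
        n_rows=4,
        n_cols=4,
        fs=50.0,
        duration=200.0,
        seed=7,
        source_node=5,
        source_gain=1.0,
        seizure_intervals=[(80.0, 100.0)],
    )
    return sz.simulate_session(cfg)


@pytest.fixture(scope="session")
def planted_session():
    """6x6 grid with a gain-3 planted source and three seizures."""
    cfg = sz.SimConfig(
        n_rows=6,
        n_cols=6,
        fs=50.0,
        duration=340.0,
        seed=11,
        source_node=14,
        source_gain=3.0,
        seizure_intervals=[(60.0, 90.0), (160.0, 190.0), (260.0, 290.0)],
    )
    return sz.simulate_session(cfg)


def random_graph(rng, n, density=1.0):
    g = rng.uniform(0.0, 1.0, size=(n, n))
    if density < 1.0:
        g *= rng.random(size=(n, n)) < density
    np.fill_diagonal(g, 0.0)
    return g
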