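"""Shared fixtures: simulated scenes reused across test modules."""

import numpy as np
import pytest

import presynquant as pq


@pytest.fixture(scope="session")
def noisy_scene():
    """Default noisy axon scene (marker + two cluster channels) with truth."""
    config = pq.SimulationConfig(seed=11)
    stack, truth = pq.generate_axon_scene(config)
    return config, stack, truth


@pytest.fixture(scope="session")
def noisefree_scene():
    """Noise-free axon scene for exact geometric checks."""
    config = pq.SimulationConfig(seed=4, poisson_gain=0.0, gaussian_sd=0.0)
    stack, truth = pq.generate_axon_scene(config)
    return config, stack, truth


@pytest.fixture(scope="session")
def noisy_axon(noisy_scene):
    _, stack, _ = noisy_scene
    return pq.segment_axon(stack.channel("axon_marker"))


@pytest.fixture(scope="session")
def cell_scene():
    config = pq.SimulationConfig(seed=3, pixel_size_nm=100.0, background=5.0)
    img, truth = pq.generate_cell_scene(config, n_filopodia=12)
    return img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
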