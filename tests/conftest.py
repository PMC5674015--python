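import numpy as np
import pytest

from histolearn import SimConfig, simulate_benchmark, simulate_slide


SMALL_CONFIG = SimConfig(
    seed=11,
    n_slides=3,
    n_objects=600,
    positive_prevalence=0.05,
    validation_per_class=25,
)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small multi-slide benchmark shared across learner tests."""
    slides, store, truth, validation = simulate_benchmark(SMALL_CONFIG)
    return slides, store, truth, validation


@pytest.fixture(scope="session")
def small_slide():
    """One simulated slide with metadata and ground truth."""
    meta, store, truth = simulate_slide(SMALL_CONFIG, 0)
    return meta, store, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
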