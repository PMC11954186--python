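import numpy as np
import pytest

from mtseason import MarkerEffect, SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_cohort():
    """Deterministic cohort with effectively no residual noise."""
    cfg = SimulationConfig(
        n_individuals=1200,
        seed=42,
        amplitude_true=0.5,
        acrophase_true=0.0,
        noise_sd=1e-12,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture
def default_cohort():
    """Moderate cohort at realistic noise for stochastic checks."""
    cfg = SimulationConfig(n_individuals=5000, seed=7, amplitude_true=0.3, noise_sd=1.0)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


def make_marker_cohort(seed=0, n=1200, noise=1e-12, amplitude=0.5, acrophase=0.0,
                       **marker_kwargs):
    cfg = SimulationConfig(
        n_individuals=n, seed=seed, amplitude_true=amplitude,
        acrophase_true=acrophase, noise_sd=noise,
        marker_effects=(MarkerEffect("m", **marker_kwargs),),
    )
    return generate_cohort(cfg)
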