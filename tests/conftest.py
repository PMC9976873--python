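import numpy as np
import pytest

from g4fret.kinetics import KineticModel
from g4fret.simulate import GeneratorConfig


@pytest.fixture
def symmetric_model() -> KineticModel:
    """All four rates equal: closed-form equilibrium is 5/12, 5x 1/12, 1/6."""
    return KineticModel(k_f=1.0, k_u=1.0, k_f2=1.0, k_u2=1.0)


@pytest.fixture
def folding_model() -> KineticModel:
    """Rates of the order seen in slow sodium-buffer folding (fast first
    nucleation, faster second folding, slow unfolding)."""
    return KineticModel(k_f=0.05, k_u=0.005, k_f2=0.2, k_u2=0.002)


@pytest.fixture
def clean_config() -> GeneratorConfig:
    """Distortions on, but no noise, background or bleaching, zero emission
    width: the exactly invertible rendering regime."""
    emission = {s: (mu, 0.0) for s, mu in zip(
        ("U", "P2", "P3", "P4", "P5", "P6", "F"),
        (0.2, 0.4, 0.4, 0.4, 0.4, 0.4, 0.8),
    )}
    return GeneratorConfig(
        noise_sd=0.0,
        background=(0.0, 0.0, 0.0),
        donor_bleach_rate=0.0,
        acceptor_bleach_rate=0.0,
        state_emission=emission,
    )


def random_model(rng: np.random.Generator, lo: float = 0.01, hi: float = 10.0) -> KineticModel:
    """Random rate draw, log-uniform over [lo, hi]."""
    k = np.exp(rng.uniform(np.log(lo), np.log(hi), size=4))
    return KineticModel(k_f=k[0], k_u=k[1], k_f2=k[2], k_u2=k[3])
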