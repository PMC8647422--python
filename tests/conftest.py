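import math

import numpy as np
import pytest
from hypothesis import settings

from jetflow.phantom import JetSpec, PhantomConfig, generate_jet_phantom

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_phantom():
    """Default 16 mL noisy phantom (seed 0) shared across read-only tests."""
    config = PhantomConfig(seed=0)
    field, truth = generate_jet_phantom(config)
    return config, field, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom for exactness checks."""
    config = PhantomConfig(seed=0, noise_sd=0.0)
    field, truth = generate_jet_phantom(config)
    return config, field, truth


@pytest.fixture(scope="session")
def two_jet_phantom():
    """Two simultaneous jets of 10 and 7 mL with distinct axes."""
    config = PhantomConfig(
        jet=JetSpec(target_volume=10.0),
        second_jet=JetSpec(
            orifice_center=(65.0, 60.0, 25.0),
            axis=np.array([-1.0, 1.0, 2.0]),
            target_volume=7.0,
        ),
        seed=5,
    )
    field, truth = generate_jet_phantom(config)
    return config, field, truth


@pytest.fixture(scope="session")
def no_jet_phantom():
    """Noise-only phantom: no regurgitation."""
    config = PhantomConfig(jet=JetSpec(target_volume=0.0), seed=7)
    field, truth = generate_jet_phantom(config)
    return config, field, truth


def aliased_jet_config(seed: int = 11) -> PhantomConfig:
    """Wide Gaussian jet at 180 cm/s peak on a near-axis-aligned direction.

    Per-component VENC wrapping needs a velocity component beyond VENC,
    so the jet axis is chosen close to one encoding axis.
    """
    sigma = 8.0 / 2.0
    qmax = 180.0 * 0.01 * 2.0 * math.pi * sigma**2 * (1.0 - math.exp(-4.5))
    jet = JetSpec(
        profile="gaussian",
        core_radius=8.0,
        peak_flow_rate=qmax,
        target_volume=None,
        axis=np.array([1.0, 1.0, 4.0]),
    )
    return PhantomConfig(jet=jet, seed=seed)


@pytest.fixture(scope="session")
def aliased_phantom():
    config = aliased_jet_config()
    field, truth = generate_jet_phantom(config)
    return config, field, truth
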