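from dataclasses import replace

import numpy as np
import pytest

from oeica.datatypes import GasProtocol
from oeica.phantom import PhantomConfig, generate_phantom, noise_free


@pytest.fixture(scope="session")
def short_protocol() -> GasProtocol:
    """Compressed gas schedule for fast tests: T = 100 dynamics, 20 baseline."""
    return GasProtocol(baseline_s=30.0, gas_period_s=30.0, n_cycles=2, dynamic_interval_s=1.5)


@pytest.fixture(scope="session")
def small_config(short_protocol) -> PhantomConfig:
    """Small, fully confounded phantom for unit tests."""
    return PhantomConfig(shape=(2, 24, 24), protocol=short_protocol, tau_s=5.0, seed=7)


@pytest.fixture(scope="session")
def clean_config(small_config) -> PhantomConfig:
    """Same geometry, no noise or physiological confounds, square-wave gas response."""
    return replace(noise_free(small_config), tau_s=0.0)


@pytest.fixture(scope="session")
def clean_phantom(clean_config):
    return generate_phantom(clean_config)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def three_temporal_sources(n_dynamics: int = 180) -> np.ndarray:
    """Sinusoid, ramp, square wave — mutually decorrelated.

    Raw sine/ramp/square waveforms are correlated on a finite window, which
    caps how well any unmixing can recover them; the ICA source model assumes
    uncorrelated sources, so the ramp is orthogonalised against the other two
    (it remains monotone-trend-like).  Each source is returned zero-mean,
    unit-variance.
    """
    t = np.linspace(0, 1, n_dynamics)
    sine = np.sin(2 * np.pi * 7 * t)
    square = np.sign(np.sin(2 * np.pi * 3 * t))
    ramp = t - t.mean()
    for other in (sine - sine.mean(), square - square.mean()):
        ramp = ramp - (ramp @ other) / (other @ other) * other
    sources = np.vstack([sine, ramp, square])
    sources = sources - sources.mean(axis=1, keepdims=True)
    return sources / sources.std(axis=1, keepdims=True)
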