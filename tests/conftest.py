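"""Shared fixtures and random-parameter factories."""

from __future__ import annotations

import numpy as np
import pytest

from tcrtrigger import ScaledParameters, get_preset


def random_params(rng: np.random.Generator, n: int | None = None) -> ScaledParameters:
    """A random valid scaled parameter set spanning the physiologic ranges."""
    gamma_off = rng.uniform(0.1, 1.0)
    return ScaledParameters(
        m_T=rng.uniform(0.1, 20.0),
        x_T=rng.uniform(0.0, 100.0),
        r_T=rng.uniform(0.1, 20.0),
        alpha=rng.uniform(0.1, 10.0),
        delta=rng.uniform(0.0, 100.0),
        nu=rng.uniform(0.0, 10.0),
        kappa=rng.uniform(0.2, 5.0),
        gamma_off=gamma_off,
        gamma_kin=rng.uniform(0.05, 1.0) * gamma_off,
        gamma_R=rng.uniform(0.1, 1.0),
        n=int(rng.integers(1, 150)) if n is None else n,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130329)


@pytest.fixture
def fig2_params() -> ScaledParameters:
    return get_preset("fig2").params


@pytest.fixture
def fig5_preset():
    return get_preset("fig5")
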