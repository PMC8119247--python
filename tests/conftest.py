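"""Shared fixtures: phantoms are generated at test time, never stored."""

from __future__ import annotations

import numpy as np
import pytest

from pmct_overview import AlgorithmConfig, CTVolume, generate_phantom, standard_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return standard_fixtures()


@pytest.fixture(scope="session")
def default_config():
    return AlgorithmConfig()


@pytest.fixture(scope="session")
def body_with_gas(fixtures):
    return generate_phantom(fixtures["body_with_gas"])


@pytest.fixture(scope="session")
def body_with_metal(fixtures):
    return generate_phantom(fixtures["body_with_metal"])


@pytest.fixture(scope="session")
def body_with_hollow_table(fixtures):
    return generate_phantom(fixtures["body_with_hollow_table"])


@pytest.fixture(scope="session")
def open_airway(fixtures):
    return generate_phantom(fixtures["open_airway"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_volume(rng, shape, lo=-1100.0, hi=3300.0) -> CTVolume:
    """A volume of uniform-random HU — worst case for projection oracles."""
    return CTVolume(rng.uniform(lo, hi, size=shape), (1.0, 1.0, 1.0))
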