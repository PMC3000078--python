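"""Shared fixtures: the reference two-domain model and synthetic sets.

Session-scoped where generation or peeling is expensive; all synthetic
data comes from the seeded generators so every test asserts against the
truth record, never against hard-coded parameter copies.
"""

import numpy as np
import pytest

from calorikin import (
    DomainModel,
    KineticParameters,
    OneStageDomain,
    TwoStageDomain,
    peel_transitions,
    simulate_model,
)
from calorikin.kinetics import default_grid
from calorikin.synth import GeneratorConfig, make_thermogram_set, s1a1_model


@pytest.fixture(scope="session")
def s1_model() -> DomainModel:
    return s1a1_model()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def native_excess(s1_model, grid):
    """Noiseless, baseline-free excess curve of the reference model."""
    return simulate_model(s1_model, grid, 1.0)


@pytest.fixture(scope="session")
def native_peel(native_excess):
    return peel_transitions(native_excess, 1.0)


@pytest.fixture(scope="session")
def noiseless_set():
    cfg = GeneratorConfig(noise_fraction=0.0)
    return cfg, make_thermogram_set(cfg, seed=11)


@pytest.fixture(scope="session")
def noisy_set():
    cfg = GeneratorConfig()
    return cfg, make_thermogram_set(cfg, seed=11)


@pytest.fixture
def single_domain_model() -> DomainModel:
    return DomainModel((OneStageDomain(KineticParameters(300.0, 320.0), 150.0),))


@pytest.fixture
def two_transition_model() -> DomainModel:
    return DomainModel((
        OneStageDomain(KineticParameters(300.0, 315.0), 300.0),
        OneStageDomain(KineticParameters(350.0, 325.0), 400.0),
    ))
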