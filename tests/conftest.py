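"""Shared fixtures: one small synthetic world reused across test modules."""

from __future__ import annotations

import pytest

from degenamp.simulate import (
    SimulationConfig,
    build_package_from_synthetic,
    make_paralog_library,
    make_reference_library,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def synthetic_library(sim_config):
    return make_reference_library(sim_config)


@pytest.fixture(scope="session")
def package(synthetic_library):
    return build_package_from_synthetic(synthetic_library)


@pytest.fixture(scope="session")
def paralog_library():
    lib, truth = make_paralog_library(100, seed=3, near_miss_fraction=0.06)
    return lib, truth
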