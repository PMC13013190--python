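"""Shared fixtures: seeded RNGs and cached scenario runs.

Scenario runs are expensive (seconds each), so each shipped config is run
at most once per session and shared across tests; reproducibility tests
run their own second copies.
"""

from __future__ import annotations

import numpy as np
import pytest

from tmesim.config import load_fixture
from tmesim.simulation import RunResult, run

_RUN_CACHE: dict[str, RunResult] = {}


def get_run(name: str) -> RunResult:
    if name not in _RUN_CACHE:
        _RUN_CACHE[name] = run(load_fixture(name))
    return _RUN_CACHE[name]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def untreated_run() -> RunResult:
    return get_run("untreated")


@pytest.fixture(scope="session")
def radiotherapy_run() -> RunResult:
    return get_run("radiotherapy")


@pytest.fixture(scope="session")
def ddri_run() -> RunResult:
    return get_run("ddri")


@pytest.fixture(scope="session")
def chemotherapy_run() -> RunResult:
    return get_run("chemotherapy")
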