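"""Shared fixtures: small synthetic cohorts with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from avalanchestates import AvalancheStateModel
from avalanchestates.synthetic import SimulationParams, simulate_cohort

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, database=None
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A 4-subject, 30-region, 4-state cohort in fixture mode (exact truth)."""
    return SimulationParams(
        n_regions=30,
        n_states=4,
        regions_per_state=6,
        duration=60.0,
        n_subjects=4,
        event_rate=0.8,
        self_transition_bias=0.35,
        fixture_mode=True,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    signals, truth = small_cohort
    res = AvalancheStateModel(signals, k=truth.n_states).fit(seed=7)
    return res, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
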