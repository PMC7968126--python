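"""Shared fixtures: session-scoped synthetic trials keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from exogait import STUDY_COHORT
from exogait.synth import GaitGenConfig, generate_trial, make_condition_set


def noiseless_config(profile_id: str = "P5", **overrides) -> GaitGenConfig:
    """A fully deterministic trial config: no jitter, no sensor noise,
    no step-time variability."""
    defaults = dict(
        profile=STUDY_COHORT[profile_id],
        step_time_cv=0.0,
        contact_jitter_sd_s=0.0,
        fsr_noise_sd=0.0,
        marker_noise_sd_m=0.0,
        duration_s=30.0,
        seed=1,
    )
    defaults.update(overrides)
    return GaitGenConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_trial():
    """P5 (0.50 m/s), 0.7 s mean step time -> every true step 0.35 m."""
    return generate_trial(
        noiseless_config("P5", mean_step_length_m=(0.35, 0.35))
    )


@pytest.fixture(scope="session")
def jitter_trial():
    """P1 (1.0 m/s) with 5 ms contact jitter, ~200 steps."""
    cfg = GaitGenConfig(
        profile=STUDY_COHORT["P1"],
        contact_jitter_sd_s=0.005,
        duration_s=120.0,
        seed=11,
    )
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def condition_set():
    """P1 baseline/assist/bf_assist set, 60 s each."""
    return make_condition_set(
        STUDY_COHORT["P1"], (101, 102, 103), duration_s=60.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
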