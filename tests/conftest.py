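"""Shared fixtures: a desk-scale synthetic cohort, reused (session scope)
by the windowing, feature and evaluation tests."""

from __future__ import annotations

import pytest

from physioemo.pipeline import cohort_features, default_scaled_down_config
from physioemo.synthio import generate_cohort

COHORT_SEED = 20260928


@pytest.fixture(scope="session")
def run_config():
    cfg = default_scaled_down_config(seed=COHORT_SEED)
    cfg.frame_lengths = (30,)
    return cfg


@pytest.fixture(scope="session")
def cohort(run_config):
    """12 subjects x 3 conditions x 12-min sessions, hotspot minutes 4-9."""
    return generate_cohort(run_config.cohort)


@pytest.fixture(scope="session")
def cohort_tables(cohort, run_config):
    """(feature tables by frame length, per-session window info)."""
    return cohort_features(cohort, run_config)


@pytest.fixture(scope="session")
def frames30(cohort_tables):
    return cohort_tables[0][30]
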