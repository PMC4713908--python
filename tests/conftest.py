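"""Shared fixtures: small simulated subjects reused across test modules."""

import pandas as pd
import pytest

from adherescope.pipeline import derive_subject
from adherescope.synthetic import PhenotypeConfig, load_preset, simulate_subject

START = pd.Timestamp("2015-01-05")


@pytest.fixture(scope="session")
def consistent_subject():
    cfg = load_preset("consistent", seed=11, patch_dropout_day_prob=0.0)
    return simulate_subject(cfg, 42)


@pytest.fixture(scope="session")
def consistent_derived(consistent_subject):
    record, truth = consistent_subject
    return derive_subject(record, truth=truth)


@pytest.fixture(scope="session")
def erratic_subject():
    cfg = load_preset("erratic", seed=7)
    return simulate_subject(cfg, 37)


@pytest.fixture()
def clean_config():
    """A plain phenotype with every nuisance process switched off."""
    return PhenotypeConfig(
        subject_id="clean",
        p_take_morning=1.0,
        p_take_evening=1.0,
        timing_jitter_sd=0.0,
        disturbance_rate=0.0,
        patch_dropout_day_prob=0.0,
        extra_dose_prob=0.0,
        coupling_beta=0.0,
        seed=3,
    )
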