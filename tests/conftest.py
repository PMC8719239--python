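"""Shared fixtures: small synthetic cohorts and pre-built daily series."""

from __future__ import annotations

import numpy as np
import pytest

from graftcast.data_io import Cohort, Measurement, PatientRecord
from graftcast.preprocess import to_daily_series
from graftcast.simulate import SyntheticConfig, fixture_configs, generate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic recovery curves, no DGF, no injuries (N=200)."""
    cfg = fixture_configs(1)["noiseless-recovery"]
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_series(noiseless_cohort):
    cohort, _ = noiseless_cohort
    series, exclusions = to_daily_series(cohort, 90)
    assert not exclusions
    return series


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """A small cohort under the calibrated default noise conditions."""
    cfg = SyntheticConfig(n_patients=40, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_noisy_series(small_noisy_cohort):
    cohort, _ = small_noisy_cohort
    series, _ = to_daily_series(cohort, 90)
    return series


def make_tiny_cohort(values_by_patient: dict[str, dict[int, float]]) -> Cohort:
    """Hand-built cohort: {patient: {day: egfr}}."""
    patients = [
        PatientRecord(pid, 50.0, "male", black_race=False) for pid in values_by_patient
    ]
    measurements = [
        Measurement(pid, day, egfr=val)
        for pid, obs in values_by_patient.items()
        for day, val in sorted(obs.items())
    ]
    return Cohort(patients, measurements)


@pytest.fixture
def tiny_cohort_factory():
    return make_tiny_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
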