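from datetime import datetime

import hypothesis
import numpy as np
import pytest

from h2slog import DeviceMeta, ReadingBlock, SessionLog, SyntheticConfig, simulate_cohort

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("suite")

#: coded concentrations exercising every censoring/band boundary
CODED_VALUES = (0.0, 1.6, 2.0, 4.8, 5.0, 5.1, 9.9, 10.0, 10.1, 50.0, 100.0, 101.0)


@pytest.fixture(scope="session")
def device() -> DeviceMeta:
    return DeviceMeta(serial_id="BW-TEST")


@pytest.fixture
def make_session(device):
    """Session factory from already-coded values."""

    def _make(values, start=datetime(2019, 1, 7, 8, 0), person="W1", seg="plant", dev=None):
        return SessionLog(dev or device, person, seg, start, [ReadingBlock(np.asarray(values, float))])

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A few hundred person-days with elevated rates, for fast module tests."""
    cfg = SyntheticConfig(
        n_workers={"sewerage_net": 3, "plant": 3, "pumping_station": 2, "water_net": 2},
        p_detect_day={"sewerage_net": 0.3, "plant": 0.3, "pumping_station": 0.3, "water_net": 0.2},
        n_workdays=40,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort at the study's conditions (~7100 days, detect rate 0.18).

    Used by the recovery and variance-decomposition checks; built once
    per test session.
    """
    cfg = SyntheticConfig(
        p_detect_day={s: 0.18 for s in ("sewerage_net", "plant", "pumping_station", "water_net")},
        p_cv_given_detect=0.33,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_metrics(study_cohort):
    from h2slog import assemble_person_days, compute_day_metrics

    return compute_day_metrics(assemble_person_days(study_cohort.sessions))
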