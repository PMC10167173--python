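import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wardalert.cohort import Admission, ClinicalEvent, VITAL_CHANNELS, empty_observations
from wardalert.scoring import EwsTable, ReferenceVitalsModel
from wardalert.synthetic import CohortParams, generate_cohort

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_admission(admission_id="M00000", los_min=2880, sample_times=None,
                   channel_values=None, events=None, observations=None):
    """Hand-built admission for unit tests.

    ``channel_values`` maps channel -> array aligned with ``sample_times``;
    unmentioned channels default to a stable normal value.
    """
    defaults = {"hr": 78.0, "rr": 16.0, "spo2": 96.0, "sbp": 122.0, "skin_temp": 36.4}
    if sample_times is None:
        sample_times = np.arange(0, los_min)
    sample_times = np.asarray(sample_times, dtype="int64")
    data = {"t_min": sample_times}
    for ch in VITAL_CHANNELS:
        if channel_values and ch in channel_values:
            data[ch] = np.asarray(channel_values[ch], dtype=float)
        else:
            data[ch] = np.full(len(sample_times), defaults[ch])
    if events is None:
        events = [ClinicalEvent(los_min, "discharge")]
    return Admission(admission_id=admission_id, length_of_stay_min=los_min,
                     samples=pd.DataFrame(data),
                     observations=observations if observations is not None else empty_observations(),
                     events=events)


@pytest.fixture(scope="session")
def ews_table():
    return EwsTable.default()


@pytest.fixture(scope="session")
def ref_model():
    return ReferenceVitalsModel.default()


@pytest.fixture(scope="session")
def small_cohort():
    """60 short-stay admissions for structural tests (not parameter recovery)."""
    return generate_cohort(CohortParams(n_admissions=60, los_median_h=72, seed=11))
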