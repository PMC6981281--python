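import numpy as np
import pandas as pd
import pytest

from necrokinetics import DeathModelParams, NecrosisTimeCourse


@pytest.fixture
def printed_params() -> DeathModelParams:
    """The reference fitted parameter set (cells, ratio, days)."""
    return DeathModelParams(n0=30.3, r=0.141, period_days=31.0, onset_days=31.0)


@pytest.fixture
def study_times() -> np.ndarray:
    """Sampled ages: 1, 3, 6, 12 and 18 months in days."""
    return np.array([31.0, 92.0, 184.0, 368.0, 552.0])


def make_timecourse(times, counts_per_time) -> NecrosisTimeCourse:
    """Build a NecrosisTimeCourse from {time: [field counts]} pairs."""
    rows = []
    for t, counts in zip(times, counts_per_time):
        for i, c in enumerate(counts):
            rows.append({"time_days": float(t), "field_id": f"t{t}_f{i}", "count": c})
    return NecrosisTimeCourse(records=pd.DataFrame(rows))


@pytest.fixture
def timecourse_factory():
    return make_timecourse
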