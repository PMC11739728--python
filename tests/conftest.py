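import numpy as np
import pandas as pd
import pytest

from cannasense import (
    CohortConfig, ParticipantData, PipelineConfig, RawCohort, run_pipeline,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cfg():
    return CohortConfig(n_participants=4, n_days=10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(CohortConfig(n_participants=2, n_days=3, seed=11))


@pytest.fixture(scope="session")
def trained_bundle(small_cohort):
    """A trained mobifit model on the small cohort (truth stripped)."""
    cfg = PipelineConfig(variant="mobifit", seed=1, n_trials=3)
    model, splits, audit = run_pipeline(small_cohort.drop_truth(), cfg)
    return {"model": model, "splits": splits, "audit": audit, "config": cfg}


def minute_grid_participant(pid="p0", offset=0.0, day=19422, hours=(17, 23),
                            hr=70.0):
    """Hand-built participant with flat per-minute HR/steps over a local
    evening span — enough coverage for window alignment and labeling."""
    lo = int(day * 86400 + hours[0] * 3600 - offset * 3600)
    hi = int(day * 86400 + hours[1] * 3600 - offset * 3600)
    ts = np.arange(lo, hi, 60, dtype=np.int64)
    streams = {
        "hr": pd.DataFrame({"ts": ts, "bpm": np.full(ts.size, hr)}),
        "steps": pd.DataFrame({"ts": ts, "steps": np.zeros(ts.size, int)}),
    }
    reports = pd.DataFrame(columns=[
        "report_id", "participant", "report_type", "report_time",
        "start_time", "end_time", "rating", "used_since_last",
        "hours_since_last_use"])
    return ParticipantData(participant=pid, utc_offset_hours=offset,
                           streams=streams, reports=reports)


@pytest.fixture
def evening_cohort():
    return RawCohort({"p0": minute_grid_participant()})
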