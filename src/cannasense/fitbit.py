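"""Wearable-derived window and daily features.

Heart-rate features are computed only from samples at or above 40 bpm
(readings strictly below 40 bpm are treated as sensor artifacts and
removed before any statistic).  Distribution-shape features use the
moment-based skewness coefficient g1 and excess kurtosis, so a normal HR
distribution scores 0 on both.  Resting HR is the mean heart rate over a
maximal zero-step run longer than 5 minutes that overlaps the window.

Prior-night sleep is attached by a noon-boundary rule: a window on local
calendar day d receives the most recent sleep record ending at or before
noon of day d, which attributes post-midnight sleep onsets (up to ~4 AM)
to the night they belong to.  Sleep start time is encoded as hours after
noon (23:00 -> 11.0, 03:30 -> 15.5) so one night's onsets are monotone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    DAY_SEC, MINUTE_SEC, WINDOW_SEC, ParticipantData, local_day, window_floor,
)

HR_MIN_VALID_BPM = 40.0
RESTING_RUN_MIN = 5  # run must be strictly longer than this many minutes

#: documented feature-dictionary order; hr_min leads its stat family so the
#: pipeline's keep-first correlation pruning preserves the minimum-HR marker
FITBIT_FEATURES = [
    "hr_min", "hr_sd", "hr_avg", "hr_med", "hr_max",
    "hr_skewness", "hr_kurtosis", "resting_hr", "sum_moving_minutes",
    "sleep_total_duration", "sleep_minutes_awake", "sleep_start_time",
]

SLEEP_FEATURES = ["sleep_total_duration", "sleep_minutes_awake",
                  "sleep_start_time"]


def exclude_hr_outliers(bpm) -> np.ndarray:
    """Drop readings strictly below 40 bpm; a reading of exactly 40 stays."""
    v = np.asarray(bpm, dtype=float)
    return v[v >= HR_MIN_VALID_BPM]


def hr_moments(bpm) -> tuple[float, float]:
    """(skewness g1, excess kurtosis) of valid HR samples; NaN below n=3
    or for a degenerate (zero-variance) sample."""
    v = exclude_hr_outliers(bpm)
    if v.size < 3 or np.ptp(v) == 0:
        return np.nan, np.nan
    return (float(stats.skew(v, bias=True)),
            float(stats.kurtosis(v, fisher=True, bias=True)))


def zero_step_runs(steps_df: pd.DataFrame) -> pd.DataFrame:
    """Maximal runs of consecutive observed minutes with zero steps.

    Only runs strictly longer than ``RESTING_RUN_MIN`` minutes qualify for
    resting HR.  A gap in the per-minute record breaks a run (the unobserved
    minutes' activity is unknown).  Returns columns (start, end, minutes)
    with ``end`` the timestamp of the run's last minute.
    """
    df = steps_df.sort_values("ts", kind="stable")
    ts = df["ts"].to_numpy(dtype=np.int64)
    zero = df["steps"].to_numpy() == 0
    runs = []
    i = 0
    n = ts.size
    while i < n:
        if not zero[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and zero[j + 1]
               and ts[j + 1] - ts[j] == MINUTE_SEC):
            j += 1
        minutes = j - i + 1
        if minutes > RESTING_RUN_MIN:
            runs.append((ts[i], ts[j], minutes))
        i = j + 1
    return pd.DataFrame(runs, columns=["start", "end", "minutes"])


def resting_hr(hr_df: pd.DataFrame, steps_df: pd.DataFrame,
               window_start: int) -> float:
    """Mean valid HR over the qualifying zero-step run that overlaps the
    window most; NaN when no such run overlaps."""
    runs = zero_step_runs(steps_df)
    return _resting_from_runs(_runs_with_hr(runs, hr_df), window_start)


def _runs_with_hr(runs: pd.DataFrame, hr_df: pd.DataFrame) -> pd.DataFrame:
    """Annotate each run with its mean valid HR (NaN when none observed)."""
    hr = hr_df.sort_values("ts", kind="stable")
    ts = hr["ts"].to_numpy(dtype=np.int64)
    bpm = hr["bpm"].to_numpy(dtype=float)
    valid = bpm >= HR_MIN_VALID_BPM
    means = []
    for s, e in zip(runs["start"], runs["end"]):
        i, j = np.searchsorted(ts, [s, e + MINUTE_SEC])
        v = bpm[i:j][valid[i:j]]
        means.append(float(v.mean()) if v.size else np.nan)
    out = runs.copy()
    out["mean_hr"] = means
    return out


def _resting_from_runs(runs: pd.DataFrame, window_start: int) -> float:
    if len(runs) == 0:
        return np.nan
    w_lo, w_hi = window_start, window_start + WINDOW_SEC
    overlap = (np.minimum(runs["end"].to_numpy() + MINUTE_SEC, w_hi)
               - np.maximum(runs["start"].to_numpy(), w_lo))
    if overlap.max() <= 0:
        return np.nan
    return float(runs["mean_hr"].to_numpy()[int(np.argmax(overlap))])


def moving_minutes(steps_df: pd.DataFrame, window_start: int) -> float:
    """Minutes in the window with a positive step count (0-5)."""
    m = ((steps_df["ts"] >= window_start)
         & (steps_df["ts"] < window_start + WINDOW_SEC))
    return float((steps_df.loc[m, "steps"] > 0).sum())


def _sleep_intervals(sleep_df: pd.DataFrame) -> pd.DataFrame:
    """Absolute local start/end seconds and duration for each record.

    ``night_date`` is the local epoch-day the night belongs to; an onset
    clock hour before noon means the participant fell asleep after
    midnight, i.e. on the following calendar day.
    """
    if len(sleep_df) == 0:
        return pd.DataFrame(columns=["start_loc", "end_loc", "duration_min",
                                     "minutes_awake", "start_encoded"])
    night = sleep_df["night_date"].to_numpy(dtype=float)
    sh = sleep_df["start_hour"].to_numpy(dtype=float)
    eh = sleep_df["end_hour"].to_numpy(dtype=float)
    start_day = np.where(sh < 12, night + 1, night)
    start_loc = start_day * DAY_SEC + sh * 3600.0
    dur_h = np.mod(eh - sh, 24.0)
    return pd.DataFrame({
        "start_loc": start_loc,
        "end_loc": start_loc + dur_h * 3600.0,
        "duration_min": dur_h * 60.0,
        "minutes_awake": sleep_df["minutes_awake"].to_numpy(dtype=float),
        "start_encoded": np.mod(sh - 12.0, 24.0),
    }).sort_values("end_loc", kind="stable").reset_index(drop=True)


def prior_night_sleep(sleep_df: pd.DataFrame, window_start: int,
                      utc_offset_hours: float) -> dict[str, float]:
    """Sleep features of the most recent record ending by the window's
    local noon; NaN features when no record qualifies."""
    iv = _sleep_intervals(sleep_df)
    noon = (local_day(window_start, utc_offset_hours) * DAY_SEC + DAY_SEC / 2)
    elig = iv[iv["end_loc"] <= float(noon)]
    if len(elig) == 0:
        return {k: np.nan for k in SLEEP_FEATURES}
    rec = elig.iloc[-1]
    return {
        "sleep_total_duration": float(rec["duration_min"]),
        "sleep_minutes_awake": float(rec["minutes_awake"]),
        "sleep_start_time": float(rec["start_encoded"]),
    }


def extract_fitbit_features(pdata: ParticipantData, window_starts
                            ) -> pd.DataFrame:
    """One row of wearable features per requested window start."""
    starts = np.asarray(sorted(set(int(s) for s in window_starts)),
                        dtype=np.int64)
    hr = pdata.streams.get("hr", pd.DataFrame(columns=["ts", "bpm"]))
    steps = pdata.streams.get("steps", pd.DataFrame(columns=["ts", "steps"]))
    sleep = pdata.streams.get("sleep", pd.DataFrame())
    runs = _runs_with_hr(zero_step_runs(steps), hr)
    iv = _sleep_intervals(sleep)

    hr = hr.sort_values("ts", kind="stable")
    hr_ts = hr["ts"].to_numpy(dtype=np.int64)
    hr_bpm = hr["bpm"].to_numpy(dtype=float)
    steps_sorted = steps.sort_values("ts", kind="stable")
    st_ts = steps_sorted["ts"].to_numpy(dtype=np.int64)
    st_val = steps_sorted["steps"].to_numpy()

    rows = []
    for s in starts:
        feats: dict[str, float] = {}
        i, j = np.searchsorted(hr_ts, [s, s + WINDOW_SEC])
        v = exclude_hr_outliers(hr_bpm[i:j])
        if v.size:
            feats.update({
                "hr_avg": float(v.mean()),
                "hr_sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "hr_min": float(v.min()),
                "hr_med": float(np.median(v)),
                "hr_max": float(v.max()),
            })
            feats["hr_skewness"], feats["hr_kurtosis"] = hr_moments(v)
        else:
            for k in ("hr_avg", "hr_sd", "hr_min", "hr_med", "hr_max",
                      "hr_skewness", "hr_kurtosis"):
                feats[k] = np.nan
        feats["resting_hr"] = _resting_from_runs(runs, int(s))
        i, j = np.searchsorted(st_ts, [s, s + WINDOW_SEC])
        feats["sum_moving_minutes"] = float((st_val[i:j] > 0).sum())
        noon = local_day(s, pdata.utc_offset_hours) * DAY_SEC + DAY_SEC / 2
        elig = iv[iv["end_loc"] <= float(noon)]
        if len(elig):
            rec = elig.iloc[-1]
            feats["sleep_total_duration"] = float(rec["duration_min"])
            feats["sleep_minutes_awake"] = float(rec["minutes_awake"])
            feats["sleep_start_time"] = float(rec["start_encoded"])
        else:
            feats.update({k: np.nan for k in SLEEP_FEATURES})
        rows.append(feats)

    out = pd.DataFrame(rows, index=pd.Index(starts, name="window_start"))
    return out[FITBIT_FEATURES]
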