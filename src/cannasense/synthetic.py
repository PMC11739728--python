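"""Synthetic cohort generator.

Emulates the raw streams of a 30-day ambulatory cannabis study: smartphone
streams (GPS, accelerometer, ambient-audio inference, screen events,
Bluetooth/Wi-Fi scans, light) sampled continuously, wearable streams
(per-minute heart rate and steps, nightly sleep records), and experience-
sampling reports — self-initiated use reports carrying start/end times and a
0-10 subjective "high" rating, plus fixed-time surveys at 10:00/15:00/20:00
with a "used since last report?" item.

A hidden per-minute ground-truth intoxication trace (0-10) drives the
injected effect structure during moderate-intensive (rating >= 4) minutes:

* minimum heart rate elevated by ``effect_minhr_delta`` bpm,
* mobility displacement from home shrunk by ``effect_rg_factor`` (< 1),
* ambient noise-energy SD inflated by ``effect_noise_sd_factor`` (> 1),
* prior-night sleep drawn from the extended ``effect_sleep_hours`` band on
  days containing a moderate-intensive episode.

The trace exists only so recovery tests can stratify raw data by true state;
no downstream stage may read it.

Default magnitudes follow the study conditions the pipeline is built for:
use episodes are <= 3 h, evening-peaked (mode 22:00-23:00), reported with a
5-15 minute latency; rating frequencies follow the observed 0-10 event
distribution; heart rate rides a diurnal sinusoid around 70 bpm with an
activity-coupled term; locations are a few anchor places with Gaussian
jitter and occasional trips.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    DAY_SEC, MINUTE_SEC, ParticipantData, RawCohort, REPORT_COLUMNS,
    TRUTH_COLUMNS, log,
)

# Observed event frequencies used as sampling weights ------------------------

#: rating 0..10 -> relative frequency of self-initiated reports
RATING_WEIGHTS = (28, 9, 9, 17, 14, 14, 17, 10, 7, 4, 0)

#: episode start clock hour (0..23) -> relative frequency (evening-peaked,
#: mode 22:00-23:00)
START_HOUR_WEIGHTS = (7, 8, 2, 0, 0, 0, 0, 1, 0, 5, 8, 2,
                      6, 6, 5, 4, 3, 4, 5, 6, 7, 10, 24, 16)

#: (low_min, high_min, weight) duration buckets, all <= 180 minutes
DURATION_BUCKETS = ((0, 30, 54), (30, 60, 20), (60, 90, 23),
                    (90, 120, 13), (120, 150, 13), (150, 180, 6))

#: local-day index of the simulated study start (a Monday)
START_EPOCH_DAY = 19422

_METERS_PER_DEG = 111_320.0


@dataclass
class CohortConfig:
    """Study-condition knobs for :func:`simulate_cohort`."""

    n_participants: int = 20
    n_days: int = 30
    seed: int = 0
    episode_rate: float = 0.6          # expected use episodes per day
    rating_distribution: tuple = tuple(w / sum(RATING_WEIGHTS)
                                       for w in RATING_WEIGHTS)
    effect_minhr_delta: float = 10.0   # bpm added during MI minutes
    effect_rg_factor: float = 0.5      # mobility shrink factor during MI
    effect_noise_sd_factor: float = 1.5
    effect_sleep_hours: tuple = (8.0, 11.0)   # prior-night band, MI days
    baseline_sleep_hours: tuple = (6.0, 8.0)
    missing_rates: dict = field(default_factory=lambda: {
        "gps": 0.05, "accel": 0.02, "audio": 0.02, "light": 0.02,
        "hr": 0.10, "steps": 0.05,
    })
    report_prob: float = 0.92          # episode -> self-initiated report
    missing_rating_prob: float = 0.01
    duplicate_prob: float = 0.02
    missing_end_prob: float = 0.02
    corrupt_duration_prob: float = 0.01  # reported end pushed past 3 h
    fixed_response_prob: float = 0.85
    utc_offset_hours: float = -5.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be >= 0")
        probs = np.asarray(self.rating_distribution, dtype=float)
        if probs.shape != (11,) or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("rating_distribution must be 11 probabilities summing to 1")
        if self.effect_rg_factor <= 0:
            raise ValueError("effect_rg_factor must be > 0")
        if self.effect_noise_sd_factor <= 0:
            raise ValueError("effect_noise_sd_factor must be > 0")
        lo, hi = self.effect_sleep_hours
        if not (0 < lo <= hi <= 24):
            raise ValueError("effect_sleep_hours must be an increasing band in (0, 24]")
        lo, hi = self.baseline_sleep_hours
        if not (0 < lo <= hi <= 24):
            raise ValueError("baseline_sleep_hours must be an increasing band in (0, 24]")
        for name, rate in self.missing_rates.items():
            if not (0 <= rate < 1):
                raise ValueError(f"missing_rates[{name!r}] must be in [0, 1)")
        for name in ("report_prob", "missing_rating_prob", "duplicate_prob",
                     "missing_end_prob", "corrupt_duration_prob",
                     "fixed_response_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# per-participant simulation
# ---------------------------------------------------------------------------

def _draw_episodes(cfg: CohortConfig, rng: np.random.Generator):
    """Evening-peaked episodes (start_loc, end_loc seconds, rating)."""
    hour_p = np.asarray(START_HOUR_WEIGHTS, dtype=float)
    hour_p /= hour_p.sum()
    dur_p = np.asarray([w for *_, w in DURATION_BUCKETS], dtype=float)
    dur_p /= dur_p.sum()
    episodes = []
    horizon = cfg.n_days * DAY_SEC
    for day in range(cfg.n_days):
        for _ in range(rng.poisson(cfg.episode_rate)):
            hour = rng.choice(24, p=hour_p)
            start = day * DAY_SEC + hour * 3600 + int(rng.uniform(0, 3600))
            lo, hi, _ = DURATION_BUCKETS[rng.choice(len(DURATION_BUCKETS), p=dur_p)]
            dur = int(rng.uniform(max(lo, 5), hi) * 60)
            end = min(start + dur, horizon)
            if end <= start:
                continue
            if any(s < end and start < e for s, e, _ in episodes):
                continue  # keep episodes disjoint
            rating = int(rng.choice(11, p=np.asarray(cfg.rating_distribution)))
            episodes.append((start, end, rating))
    episodes.sort()
    return episodes


def _sleep_records(cfg, rng, mi_days: set[int]):
    """One record per night; night n runs from evening of day n into day n+1.

    The prior night of a moderate-intensive day is drawn from the extended
    band, so the night ending on the morning of an MI day is long.
    """
    records = []
    for night in range(-1, cfg.n_days):
        start_hour = float(np.clip(rng.normal(23.3, 1.0), 21.5, 27.5))
        band = cfg.effect_sleep_hours if (night + 1) in mi_days \
            else cfg.baseline_sleep_hours
        dur_h = rng.uniform(*band)
        start_loc = night * DAY_SEC + start_hour * 3600.0
        end_loc = start_loc + dur_h * 3600.0
        records.append({
            "night_date": START_EPOCH_DAY + night,
            "start_hour": round(start_hour % 24.0, 3),
            "end_hour": round((start_hour + dur_h) % 24.0, 3),
            "minutes_awake": round(float(rng.uniform(5, 45)), 1),
            "_start_loc": start_loc,
            "_end_loc": end_loc,
        })
    return records


def _drop_rows(df, rate, rng):
    if rate <= 0 or len(df) == 0:
        return df
    keep = rng.random(len(df)) >= rate
    return df.loc[keep].reset_index(drop=True)


def _drop_hour_blocks(df, rate, rng):
    """Drop whole clock hours (wear gaps), not isolated samples."""
    if rate <= 0 or len(df) == 0:
        return df
    block = df["ts"].to_numpy(dtype=np.int64) // 3600
    uniq = np.unique(block)
    dropped = set(uniq[rng.random(uniq.size) < rate])
    keep = ~np.isin(block, list(dropped))
    return df.loc[keep].reset_index(drop=True)


def _simulate_participant(pid: str, cfg: CohortConfig,
                          rng: np.random.Generator) -> ParticipantData:
    n_min = cfg.n_days * 1440
    loc_min = np.arange(n_min, dtype=np.int64) * MINUTE_SEC  # local seconds
    hour = (loc_min % DAY_SEC) / 3600.0
    day_idx = loc_min // DAY_SEC
    weekday = (day_idx + START_EPOCH_DAY + 3) % 7  # 0=Mon (study starts Monday)
    offset_sec = cfg.utc_offset_hours * 3600.0
    base_loc = START_EPOCH_DAY * DAY_SEC

    def to_utc(loc):
        return (np.asarray(loc, dtype=float) + base_loc - offset_sec).astype(np.int64)

    # --- truth trace -------------------------------------------------------
    episodes = _draw_episodes(cfg, rng)
    truth = np.zeros(n_min, dtype=np.int64)
    for s, e, rating in episodes:
        truth[s // 60:(e + 59) // 60] = rating
    mi_minute = truth >= 4
    # every local day containing an MI minute (episodes can cross midnight)
    mi_days = set((loc_min[mi_minute] // DAY_SEC).tolist())

    # --- sleep -------------------------------------------------------------
    sleep_recs = _sleep_records(cfg, rng, mi_days)
    asleep = np.zeros(n_min, dtype=bool)
    for rec in sleep_recs:
        lo = max(int(rec["_start_loc"] // 60), 0)
        hi = min(int(rec["_end_loc"] // 60), n_min)
        if hi > lo:
            asleep[lo:hi] = True
    asleep &= ~mi_minute  # a participant mid-episode is awake
    sleep_df = pd.DataFrame(
        [{k: v for k, v in rec.items() if not k.startswith("_")}
         for rec in sleep_recs]
    )

    # --- steps -------------------------------------------------------------
    p_move = np.where((hour >= 8) & (hour < 22), 0.12, 0.05)
    moving = (rng.random(n_min) < p_move) & ~asleep
    steps = np.where(moving, rng.integers(15, 120, size=n_min), 0)

    # --- heart rate --------------------------------------------------------
    hr = (70.0 + 3.5 * np.sin(2 * np.pi * (hour - 17.0) / 24.0)
          - 3.0 * asleep + 0.06 * steps + rng.normal(0, 2.5, n_min))
    hr = hr + cfg.effect_minhr_delta * mi_minute
    hr = np.clip(hr, 45.0, 190.0)

    # --- GPS ---------------------------------------------------------------
    home = np.array([40.7 + rng.normal(0, 0.05), -74.0 + rng.normal(0, 0.05)])
    work = home + rng.normal(0, 0.02, 2)
    social = home + rng.normal(0, 0.02, 2)
    anchors = np.stack([home, work, social])
    n_blocks = n_min // 30
    block_anchor = np.zeros(n_blocks, dtype=np.int64)
    trip_offset = np.zeros((n_blocks, 2))
    for b in range(n_blocks):
        m = b * 30
        h = hour[m]
        if asleep[m]:
            a = 0
        elif 9 <= h < 17 and weekday[m] < 5:
            a = 1 if rng.random() < 0.75 else 0
        elif h >= 18:
            a = 2 if rng.random() < 0.35 else 0
        else:
            a = 0 if rng.random() < 0.9 else 2
        block_anchor[b] = a
        if rng.random() < 0.03:  # occasional trip away from any anchor
            trip_offset[b] = rng.uniform(-0.05, 0.05, 2)
    anchor_min = np.repeat(block_anchor, 30)[:n_min]
    pos = anchors[anchor_min] + np.repeat(trip_offset, 30, axis=0)[:n_min]
    pos = pos + rng.normal(0, 15.0 / _METERS_PER_DEG, (n_min, 2))
    disp = pos - home
    pos = home + np.where(mi_minute[:, None], cfg.effect_rg_factor * disp, disp)

    # --- ambient audio (2 frames / minute) ---------------------------------
    half = np.repeat(loc_min, 2) + np.tile([0, 30], n_min)
    mu_e = np.where(np.repeat(asleep, 2), 3.0,
                    18.0 + 10.0 * np.sin(2 * np.pi * (np.repeat(hour, 2) - 19.0) / 24.0))
    sd_e = 5.0 * np.where(np.repeat(mi_minute, 2), cfg.effect_noise_sd_factor, 1.0)
    energy = np.clip(mu_e + rng.normal(0, 1, half.size) * sd_e, 0.2, None)
    amplitude = np.sqrt(energy)
    from .mobile import classify_audio_frame  # shared default cutpoints
    inferred = classify_audio_frame(amplitude)

    # --- accelerometer (2 samples / minute) --------------------------------
    tilt = np.deg2rad(np.clip(rng.normal(25, 20, half.size), 0, 90))
    azim = rng.uniform(0, 2 * np.pi, half.size)
    jitter = 0.02 + 0.10 * np.repeat(moving, 2)
    ax = np.sin(tilt) * np.cos(azim) + rng.normal(0, jitter)
    ay = np.sin(tilt) * np.sin(azim) + rng.normal(0, jitter)
    az = np.cos(tilt) + rng.normal(0, jitter)

    # --- screen sessions ---------------------------------------------------
    ev_ts, ev_state = [], []
    in_session_until = -1.0
    for m in np.nonzero(~asleep)[0]:
        t = float(loc_min[m])
        if t < in_session_until:
            continue
        if rng.random() < 0.025:
            dur = float(np.clip(np.exp(rng.normal(4.6, 0.9)), 20, 1800))
            dur = min(dur, cfg.n_days * DAY_SEC - t)  # stay inside the study
            ev_ts += [t, t + dur]
            ev_state += ["unlocked", "locked"]
            in_session_until = t + dur
    screen_df = pd.DataFrame({"ts": to_utc(np.asarray(ev_ts)),
                              "state": ev_state})

    # --- scans & light -----------------------------------------------------
    scan_loc = np.arange(0, cfg.n_days * DAY_SEC, 300, dtype=np.int64)
    scan_hour = (scan_loc % DAY_SEC) / 3600.0
    scan_block = np.minimum(scan_loc // (30 * 60), n_blocks - 1)
    evening = (scan_hour >= 18) | (scan_hour < 2)
    bt_counts = rng.poisson(np.where(evening, 3.0, 1.0))
    ap_names = {0: "ap_home", 1: "ap_work", 2: "ap_social"}
    ap_ids = [f"{ap_names[int(block_anchor[b])]}_{pid}" for b in scan_block]
    lux = np.where((hour >= 7) & (hour < 20), rng.uniform(100, 900, n_min),
                   rng.uniform(2, 80, n_min))
    lux = np.where(asleep, rng.uniform(0, 3, n_min), lux)

    # --- assemble stream tables -------------------------------------------
    streams = {
        "gps": pd.DataFrame({"ts": to_utc(loc_min),
                             "lat": np.round(pos[:, 0], 7),
                             "lon": np.round(pos[:, 1], 7)}),
        "accel": pd.DataFrame({"ts": to_utc(half), "ax": np.round(ax, 4),
                               "ay": np.round(ay, 4), "az": np.round(az, 4)}),
        "audio": pd.DataFrame({"ts": to_utc(half),
                               "amplitude": np.round(amplitude, 4),
                               "inferred_class": inferred}),
        "screen": screen_df,
        "bluetooth": pd.DataFrame({"ts": to_utc(scan_loc),
                                   "device_count": bt_counts}),
        "wifi": pd.DataFrame({"ts": to_utc(scan_loc), "ap_id": ap_ids}),
        "light": pd.DataFrame({"ts": to_utc(loc_min), "lux": np.round(lux, 1)}),
        "hr": pd.DataFrame({"ts": to_utc(loc_min), "bpm": np.round(hr, 1)}),
        "steps": pd.DataFrame({"ts": to_utc(loc_min), "steps": steps}),
        "sleep": sleep_df,
    }
    for name, rate in cfg.missing_rates.items():
        if name not in streams:
            continue
        dropper = _drop_hour_blocks if name == "hr" else _drop_rows
        streams[name] = dropper(streams[name], rate, rng)

    reports = _make_reports(pid, cfg, rng, episodes, to_utc)
    truth_df = pd.DataFrame({"ts": to_utc(loc_min), "rating": truth},
                            columns=TRUTH_COLUMNS)
    return ParticipantData(participant=pid,
                           utc_offset_hours=cfg.utc_offset_hours,
                           streams=streams, reports=reports, truth=truth_df)


def _make_reports(pid, cfg, rng, episodes, to_utc):
    rows = []
    # self-initiated use reports, 5-15 minutes after true start
    for i, (s, e, rating) in enumerate(episodes):
        if rng.random() > cfg.report_prob:
            continue
        start_t = float(to_utc(s))
        end_t = float(to_utc(e))
        if rng.random() < cfg.corrupt_duration_prob:
            end_t = start_t + rng.uniform(3.5, 6.0) * 3600.0
        elif rng.random() < cfg.missing_end_prob:
            end_t = np.nan
        row = {
            "report_id": f"{pid}-S{i}",
            "participant": pid,
            "report_type": "self_initiated",
            "report_time": float(to_utc(s + rng.uniform(300, 900))),
            "start_time": start_t,
            "end_time": end_t,
            "rating": (np.nan if rng.random() < cfg.missing_rating_prob
                       else float(rating)),
            "used_since_last": np.nan,
            "hours_since_last_use": np.nan,
        }
        rows.append(row)
        if rng.random() < cfg.duplicate_prob:
            dup = dict(row)
            dup["report_id"] = f"{pid}-S{i}d"
            rows.append(dup)
    # fixed-time surveys at 10:00 / 15:00 / 20:00
    from .datamodel import FIXED_PROMPT_HOURS
    prompts = [(day, h) for day in range(cfg.n_days) for h in FIXED_PROMPT_HOURS]
    prev_loc = -np.inf
    for day, h in prompts:
        prompt_loc = day * DAY_SEC + h * 3600
        used = any(prev_loc < s <= prompt_loc for s, _, _ in episodes)
        ends = [e for _, e, _ in episodes if e <= prompt_loc]
        hours_since = ((prompt_loc - max(ends)) / 3600.0) if ends else 999.0
        if rng.random() <= cfg.fixed_response_prob:
            rows.append({
                "report_id": f"{pid}-F{day}-{h}",
                "participant": pid,
                "report_type": "fixed_time",
                "report_time": float(to_utc(prompt_loc)),
                "start_time": np.nan,
                "end_time": np.nan,
                "rating": np.nan,
                "used_since_last": "yes" if used else "no",
                "hours_since_last_use": round(hours_since, 2),
            })
        prev_loc = prompt_loc
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def simulate_cohort(config: CohortConfig) -> RawCohort:
    """Generate a deterministic synthetic cohort for the given config."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    participants = {}
    for i, child in enumerate(root.spawn(config.n_participants)):
        pid = f"p{i:03d}"
        participants[pid] = _simulate_participant(
            pid, config, np.random.default_rng(child))
    log.info("simulate_cohort: %d participants x %d days (seed=%d)",
             config.n_participants, config.n_days, config.seed)
    return RawCohort(participants)
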