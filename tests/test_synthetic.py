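"""Generator contracts: determinism, degenerate configs, effect recovery.

Effect-recovery contrasts are computed directly from the hidden truth
trace, matching windows on clock hour (and wakefulness for HR) so the
generator's diurnal structure does not confound the injected deltas.
"""

import numpy as np
import pandas as pd
import pytest

from cannasense import CohortConfig, simulate_cohort
from cannasense.datamodel import WINDOW_SEC, local_hour, window_floor
from cannasense.fitbit import _sleep_intervals


def _cohort_hash(cohort):
    import hashlib
    h = hashlib.sha256()
    for pid in sorted(cohort.participants):
        p = cohort.participants[pid]
        for name in sorted(p.streams):
            h.update(p.streams[name].to_csv(index=False).encode())
        h.update(p.reports.to_csv(index=False).encode())
        h.update(p.truth.to_csv(index=False).encode())
    return h.hexdigest()


def test_seed_determinism():
    cfg = CohortConfig(n_participants=2, n_days=3, seed=7)
    assert _cohort_hash(simulate_cohort(cfg)) == _cohort_hash(simulate_cohort(cfg))


def test_different_seeds_differ():
    a = simulate_cohort(CohortConfig(n_participants=1, n_days=2, seed=1))
    b = simulate_cohort(CohortConfig(n_participants=1, n_days=2, seed=2))
    assert _cohort_hash(a) != _cohort_hash(b)


def test_zero_episode_rate_degenerate():
    cfg = CohortConfig(n_participants=2, n_days=4, seed=5, episode_rate=0.0)
    cohort = simulate_cohort(cfg)
    for p in cohort:
        r = p.reports
        assert (r["report_type"] == "self_initiated").sum() == 0
        fixed = r[r["report_type"] == "fixed_time"]
        assert (fixed["used_since_last"] == "no").all()
        assert (p.truth["rating"] == 0).all()


@pytest.mark.parametrize("field,value", [
    ("n_participants", 0),
    ("n_days", 0),
    ("episode_rate", -1.0),
    ("effect_rg_factor", 0.0),
    ("effect_noise_sd_factor", -2.0),
    ("rating_distribution", (1.0,) * 11),
])
def test_invalid_config_rejected_naming_field(field, value):
    cfg = CohortConfig(**{field: value})
    with pytest.raises(ValueError) as exc:
        cfg.validate()
    assert field.split("_")[0] in str(exc.value) or field in str(exc.value)


def _minute_table(p):
    """Per-minute truth/hour/asleep table for one participant."""
    truth = p.truth
    hour = local_hour(truth["ts"].to_numpy(), p.utc_offset_hours)
    iv = _sleep_intervals(p.streams["sleep"])
    loc = truth["ts"].to_numpy(dtype=float) + p.utc_offset_hours * 3600.0
    asleep = np.zeros(len(truth), dtype=bool)
    for s, e in zip(iv["start_loc"], iv["end_loc"]):
        asleep |= (loc >= s) & (loc < e)
    return pd.DataFrame({
        "window": window_floor(truth["ts"].to_numpy()),
        "hour": hour.astype(int),
        "mi": truth["rating"].to_numpy() >= 4,
        "asleep": asleep,
    })


def _hour_matched_contrast(values, meta):
    """(mean over fully-MI windows, mean over clean windows), hour-matched.

    Fully-MI windows avoid episode-boundary mixtures; clean windows are
    truth-0 and fully awake.  Matching on clock hour removes the diurnal
    structure the generator deliberately includes.  NaNs when a
    participant has no matched hours.
    """
    df = meta.groupby("window").agg(mi_all=("mi", "all"),
                                    mi_any=("mi", "any"),
                                    hour=("hour", "first"),
                                    asleep=("asleep", "any"))
    df["value"] = values
    df = df.dropna(subset=["value"])
    mi = df[df["mi_all"]]
    clean = df[~df["mi_any"] & ~df["asleep"]]
    per_hour = []
    for h, grp in mi.groupby("hour"):
        base = clean[clean["hour"] == h]
        if len(base) == 0:
            continue
        per_hour.append((len(grp), grp["value"].mean(), base["value"].mean()))
    if not per_hour:
        return np.nan, np.nan
    w = np.array([n for n, _, _ in per_hour], dtype=float)
    a = np.array([x for _, x, _ in per_hour])
    b = np.array([x for _, _, x in per_hour])
    return (float(np.average(a, weights=w)), float(np.average(b, weights=w)))


def test_min_hr_effect_recovery():
    """Injected minimum-HR delta is recovered from truth-stratified data."""
    cfg = CohortConfig(n_participants=10, n_days=20, seed=42,
                       effect_minhr_delta=15.0,
                       missing_rates={})
    cohort = simulate_cohort(cfg)
    mi_means, base_means = [], []
    for p in cohort:
        meta = _minute_table(p)
        hr = p.streams["hr"]
        minhr = (hr.assign(window=window_floor(hr["ts"].to_numpy()))
                 .groupby("window")["bpm"].min())
        wins = meta.groupby("window").first().index
        a, b = _hour_matched_contrast(
            minhr.reindex(wins).to_numpy(), meta)
        mi_means.append(a)
        base_means.append(b)
    delta = np.nanmean(mi_means) - np.nanmean(base_means)
    assert delta == pytest.approx(15.0, abs=2.0)


def test_mobility_shrink_recovery():
    """Radius-of-gyration ratio MI/baseline recovers the configured factor."""
    from cannasense.mobile import radius_of_gyration
    cfg = CohortConfig(n_participants=6, n_days=10, seed=43,
                       effect_rg_factor=0.5, missing_rates={})
    cohort = simulate_cohort(cfg)
    ratios = []
    for p in cohort:
        meta = _minute_table(p)
        gps = p.streams["gps"].assign(
            window=window_floor(p.streams["gps"]["ts"].to_numpy()))
        rg = gps.groupby("window").apply(
            lambda g: radius_of_gyration(g["lat"], g["lon"]),
            include_groups=False)
        wins = meta.groupby("window").first().index
        a, b = _hour_matched_contrast(rg.reindex(wins).to_numpy(), meta)
        if np.isfinite(a) and np.isfinite(b) and b > 0:
            ratios.append(a / b)
    assert np.mean(ratios) == pytest.approx(0.5, abs=0.15)


def test_noise_sd_inflation_recovery():
    """Window noise-energy SD inflates by about the configured factor."""
    cfg = CohortConfig(n_participants=8, n_days=15, seed=44,
                       effect_noise_sd_factor=2.0, missing_rates={})
    cohort = simulate_cohort(cfg)
    ratios = []
    for p in cohort:
        meta = _minute_table(p)
        au = p.streams["audio"]
        sd = (au.assign(window=window_floor(au["ts"].to_numpy()),
                        energy=au["amplitude"] ** 2)
              .groupby("window")["energy"].std())
        wins = meta.groupby("window").first().index
        a, b = _hour_matched_contrast(sd.reindex(wins).to_numpy(), meta)
        if np.isfinite(a) and np.isfinite(b) and b > 0:
            ratios.append(a / b)
    assert np.mean(ratios) == pytest.approx(2.0, rel=0.25)


def test_sleep_band_on_mi_days():
    """Nights preceding an MI day fall in the extended duration band."""
    cfg = CohortConfig(n_participants=6, n_days=20, seed=45,
                       effect_sleep_hours=(8.0, 11.0),
                       baseline_sleep_hours=(6.0, 8.0))
    cohort = simulate_cohort(cfg)
    mi_durs, base_durs = [], []
    for p in cohort:
        truth = p.truth
        day = ((truth["ts"].to_numpy() + p.utc_offset_hours * 3600)
               // 86400).astype(int)
        mi_days = set(day[truth["rating"].to_numpy() >= 4])
        iv = _sleep_intervals(p.streams["sleep"])
        for _, rec in iv.iterrows():
            end_day = int(rec["end_loc"] // 86400)
            (mi_durs if end_day in mi_days else base_durs).append(
                rec["duration_min"] / 60.0)
    assert min(mi_durs) >= 8.0 - 1e-9
    assert max(mi_durs) <= 11.0 + 1e-9
    assert np.mean(base_durs) < np.mean(mi_durs)


def test_truth_not_needed_downstream(small_cohort):
    """Stripping the hidden truth leaves the pipeline fully runnable."""
    from cannasense import PipelineConfig, build_dataset
    stripped = small_cohort.drop_truth()
    assert all(p.truth is None for p in stripped)
    X, y, _ = build_dataset(stripped, PipelineConfig(seed=0, n_trials=1))
    assert len(X) > 0 and set(y) <= {"N", "L", "MI"}


def test_report_latency_band(small_cohort):
    """Self-reports arrive 5-15 minutes after the reported start."""
    for p in small_cohort:
        si = p.reports[p.reports["report_type"] == "self_initiated"]
        lat = (si["report_time"] - si["start_time"]) / 60.0
        assert ((lat >= 5.0) & (lat <= 15.0)).all()


def test_timestamps_within_study_period(small_cohort, small_cfg):
    horizon = small_cfg.n_days * 86400
    for p in small_cohort:
        base = p.truth["ts"].min()
        for name, df in p.streams.items():
            if "ts" not in df.columns or df.empty:
                continue
            rel = df["ts"] - base
            assert rel.min() >= 0
            assert rel.max() <= horizon
        assert (p.streams["hr"]["bpm"] > 0).all()
        assert (p.streams["steps"]["steps"] >= 0).all()
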