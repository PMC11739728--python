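"""Smartphone feature oracles: each feature against a brute-force
recomputation on small slices, plus the documented edge conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cannasense import (
    classify_audio_frame, device_use_features, location_clusters,
    noise_energy, radius_of_gyration, stat_block, total_distance,
    weighted_stationary_sd,
)
from cannasense.mobile import haversine_m

M_PER_DEG_LAT = 6_371_000.0 * np.pi / 180.0


# --- radius of gyration ----------------------------------------------------

def test_rg_single_fix_is_zero():
    assert radius_of_gyration([40.0], [-74.0]) == 0.0


def test_rg_no_fixes_is_missing():
    assert np.isnan(radius_of_gyration([], []))


def test_rg_two_fixes_on_meridian():
    """Two fixes 200 m apart on one meridian sit 100 m from the centroid."""
    dlat = 200.0 / M_PER_DEG_LAT
    rg = radius_of_gyration([40.0, 40.0 + dlat], [-74.0, -74.0])
    assert rg == pytest.approx(100.0, abs=0.1)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.tuples(st.floats(-0.005, 0.005), st.floats(-0.005, 0.005)),
                min_size=1, max_size=20),
       st.floats(-1e-3, 1e-3), st.floats(-1e-3, 1e-3))
def test_rg_translation_invariant_and_matches_bruteforce(offsets, dlat, dlon):
    lat = 40.0 + np.array([o[0] for o in offsets])
    lon = -74.0 + np.array([o[1] for o in offsets])
    rg = radius_of_gyration(lat, lon)
    # brute force: per-fix haversine to the centroid, RMS
    d = [haversine_m(la, lo, lat.mean(), lon.mean()) for la, lo in zip(lat, lon)]
    assert rg == pytest.approx(float(np.sqrt(np.mean(np.square(d)))), rel=1e-9)
    assert radius_of_gyration(lat + dlat, lon + dlon) == pytest.approx(rg, abs=0.01)


# --- clustering ------------------------------------------------------------

def test_all_fixes_one_point_single_cluster():
    ts = np.arange(0, 300, 60)
    labels, dwell = location_clusters(ts, [40.0] * 5, [-74.0] * 5)
    assert set(labels) == {0}
    assert dwell[0] == 240.0  # span of member fixes


def test_far_points_two_clusters():
    labels, dwell = location_clusters([0, 60], [40.0, 40.09], [-74.0, -74.0],
                                      distance_threshold=100.0)
    assert len(dwell) == 2


def test_cluster_assignment_matches_pairwise_check():
    """Three-anchor walk: every member is within threshold of its seed and
    every new seed was out of range of the previous seed."""
    rng = np.random.default_rng(0)
    anchors = np.array([[40.0, -74.0], [40.001, -74.0], [40.0, -73.998]])
    seq = anchors[np.repeat([0, 1, 2, 0], 5)]
    pts = seq + rng.normal(0, 3.0 / M_PER_DEG_LAT, seq.shape)
    ts = np.arange(len(pts)) * 15.0
    labels, dwell = location_clusters(ts, pts[:, 0], pts[:, 1],
                                      distance_threshold=30.0)
    seeds = {}
    for i, lab in enumerate(labels):
        if lab not in seeds:
            seeds[lab] = pts[i]
            if i > 0:  # a new seed must be far from the active seed
                prev = seeds[labels[i - 1]]
                assert haversine_m(*pts[i], *prev) > 30.0
        else:
            assert haversine_m(*pts[i], *seeds[lab]) <= 30.0


def test_total_distance_bounds_displacement():
    rng = np.random.default_rng(1)
    lat = 40.0 + np.cumsum(rng.normal(0, 1e-4, 10))
    lon = -74.0 + np.cumsum(rng.normal(0, 1e-4, 10))
    ts = np.arange(10) * 30.0
    straight = haversine_m(lat[0], lon[0], lat[-1], lon[-1])
    assert total_distance(ts, lat, lon) >= straight - 1e-9


def test_wtsd_requires_stationary_fixes():
    # two fixes moving at ~37 m/s: nothing stationary
    assert np.isnan(weighted_stationary_sd(
        [0, 60], [40.0, 40.02], [-74.0, -74.0])[0])
    # dwell-weighted SD against a direct weighted computation
    ts = [0, 100, 300, 310]
    lat = [40.0, 40.0001, 40.0002, 40.0002]
    lon = [-74.0] * 4
    got_lat, got_lon = weighted_stationary_sd(ts, lat, lon)
    w = np.array([100.0, 200.0, 10.0])
    x = np.array(lat[:3])
    mu = np.average(x, weights=w)
    assert got_lat == pytest.approx(np.sqrt(np.average((x - mu) ** 2, weights=w)))
    assert got_lon == pytest.approx(0.0)


# --- audio -----------------------------------------------------------------

def test_amplitude_zero_is_silence():
    assert classify_audio_frame(0.0) == "silence"


def test_classification_respects_cutpoints():
    cp = {"silence": 1.0, "noise": 2.0, "voice": 3.0}
    got = classify_audio_frame([0.5, 1.5, 2.5, 9.0], cp)
    assert list(got) == ["silence", "noise", "voice", "unknown"]


def test_negative_amplitude_rejected():
    with pytest.raises(ValueError):
        classify_audio_frame(-1.0)


def test_noise_energy_example():
    """Amplitudes {1, 3} -> energies {1, 9}: mean 5, sample SD by formula."""
    mean, sd = noise_energy([1.0, 3.0])
    assert mean == pytest.approx(5.0)
    assert sd == pytest.approx(np.sqrt(((1 - 5) ** 2 + (9 - 5) ** 2) / 1))


def test_constant_amplitude_sd_zero():
    assert noise_energy([2.0] * 8)[1] == 0.0


def test_empty_audio_slice_missing():
    m, sd = noise_energy([])
    assert np.isnan(m) and np.isnan(sd)


# --- screen sessions -------------------------------------------------------

def _ev(*pairs):
    return pd.DataFrame({"ts": [t for t, _ in pairs],
                         "state": [s for _, s in pairs]})


def test_no_events_previously_locked():
    f = device_use_features(_ev((0, "locked")), 3000)
    assert f["unlock_minutes"] == 0.0


def test_unlocked_whole_window():
    f = device_use_features(_ev((0, "unlocked")), 3000)
    assert f["unlock_minutes"] == 5.0
    assert f["session_max"] == 300.0


def test_single_session_span_arithmetic():
    """Unlock at +60 s, lock at +240 s: one 180 s session, 3 minutes."""
    w = 64800  # 18:00
    f = device_use_features(_ev((w + 60, "unlocked"), (w + 240, "locked")), w)
    assert f["unlock_minutes"] == pytest.approx(3.0)
    assert f["session_avg"] == pytest.approx(180.0)
    assert f["session_sd"] == 0.0


def test_unmatched_unlock_clipped_at_window_end():
    w = 0
    f = device_use_features(_ev((w + 200, "unlocked")), w)
    assert f["session_max"] == pytest.approx(100.0)


# --- stat block ------------------------------------------------------------

def test_stat_block_singleton():
    s = stat_block([5.0])
    assert s["min"] == s["max"] == s["avg"] == s["med"] == 5.0
    assert s["sd"] == 0.0


def test_stat_block_example():
    s = stat_block([1.0, 2.0, 3.0, 4.0])
    assert s["med"] == 2.5
    assert s["sd"] == pytest.approx(1.2909944, abs=1e-4)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50),
       st.randoms(use_true_random=False))
def test_stat_block_matches_bruteforce_and_permutation_invariant(vals, rnd):
    s = stat_block(vals)
    v = sorted(vals)
    assert s["min"] == pytest.approx(v[0])
    assert s["max"] == pytest.approx(v[-1])
    assert s["avg"] == pytest.approx(sum(vals) / len(vals), abs=1e-6)
    assert s["min"] <= s["med"] <= s["max"]
    if len(vals) > 1:
        mu = sum(vals) / len(vals)
        assert s["sd"] == pytest.approx(
            np.sqrt(sum((x - mu) ** 2 for x in vals) / (len(vals) - 1)),
            abs=1e-6)
    shuffled = list(vals)
    rnd.shuffle(shuffled)
    assert stat_block(shuffled) == pytest.approx(s, nan_ok=True)


# --- window isolation ------------------------------------------------------

def test_features_read_only_their_window(small_cohort):
    """Perturbing samples outside a window leaves its features unchanged."""
    from cannasense.mobile import extract_mobile_features
    import copy
    p = small_cohort.participants["p000"]
    start = int(p.streams["gps"]["ts"].iloc[500] // 300 * 300)
    base = extract_mobile_features(p, [start])
    mutated = copy.deepcopy(p)
    for name in ("gps", "audio", "light"):
        df = mutated.streams[name]
        outside = (df["ts"] < start) | (df["ts"] >= start + 300)
        num_cols = [c for c in df.columns
                    if c != "ts" and df[c].dtype.kind == "f"]
        df.loc[outside, num_cols] = df.loc[outside, num_cols] * 3.0 + 1.0
    after = extract_mobile_features(mutated, [start])
    pd.testing.assert_frame_equal(base, after)
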