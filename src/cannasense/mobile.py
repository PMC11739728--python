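"""Smartphone-derived window features.

Every feature is computed strictly from the samples inside one half-open
5-minute window (screen sessions additionally use the last event before the
window to know the lock state at window start).  Windows with no samples for
a stream carry NaN for that stream's features — missingness is imputed only
at the modeling stage, because substituting zeros would fabricate silence or
stillness.

Feature families and units:

* mobility — radius of gyration (m), time at the primary location cluster
  (s), total distance traveled (m), number of clusters, and the dwell-time
  weighted SD of stationary latitude/longitude (degrees);
* movement — min/max/avg/med/SD of acceleration magnitude (g) and of the
  phone tilt angle (degrees from vertical);
* device use — unlocked minutes and min/max/avg/med/SD of interaction
  session durations (s);
* ambient audio — fractions of silence/noise/voice/unknown frames and the
  mean/SD of frame noise energy (squared amplitude);
* environment — Bluetooth device count, modal Wi-Fi access-point hash
  bucket, average and maximum lux;
* temporal — local hour of day (0-23) and day of week (0=Mon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    WINDOW_SEC, ParticipantData, day_of_week, local_hour, window_floor,
)

EARTH_RADIUS_M = 6_371_000.0

#: default amplitude cutpoints for the ambient-audio classifier
AUDIO_CUTPOINTS = {"silence": 3.0, "noise": 5.0, "voice": 6.5}

#: default distance threshold (m) for location clustering
CLUSTER_DISTANCE_M = 30.0

#: fixes slower than this (m/s) count as stationary for the weighted SD
STATIONARY_SPEED_MS = 0.5

#: number of hash buckets for the modal Wi-Fi access point encoding
WIFI_HASH_BUCKETS = 16

STAT_SUFFIXES = ("min", "max", "avg", "med", "sd")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters between coordinate pairs (degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def stat_block(values) -> dict[str, float]:
    """min/max/avg/med/sample-SD of a value list; all NaN when empty."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {s: np.nan for s in STAT_SUFFIXES}
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "avg": float(v.mean()),
        "med": float(np.median(v)),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }


def radius_of_gyration(lat, lon) -> float:
    """RMS great-circle distance of fixes from their centroid (m).

    NaN with no fixes; a single fix gives 0.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        return np.nan
    d = haversine_m(lat, lon, lat.mean(), lon.mean())
    return float(np.sqrt(np.mean(d ** 2)))


def location_clusters(ts, lat, lon,
                      distance_threshold: float = CLUSTER_DISTANCE_M):
    """Sequentially group time-ordered fixes into distance-based clusters.

    A fix within ``distance_threshold`` meters of the current cluster's seed
    (its first fix) joins that cluster; otherwise it seeds a new one.
    Returns (cluster index per fix, dwell seconds per cluster).  Dwell is the
    time span of a cluster's member fixes, so single-fix clusters dwell 0.
    """
    ts = np.asarray(ts, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    order = np.argsort(ts, kind="stable")
    ts, lat, lon = ts[order], lat[order], lon[order]
    labels = np.empty(ts.size, dtype=np.int64)
    seeds: list[tuple[float, float]] = []
    current = -1
    for i in range(ts.size):
        if current >= 0 and haversine_m(lat[i], lon[i], *seeds[current]) <= distance_threshold:
            labels[i] = current
            continue
        seeds.append((lat[i], lon[i]))
        current = len(seeds) - 1
        labels[i] = current
    dwell = np.array([ts[labels == c].max() - ts[labels == c].min()
                      for c in range(len(seeds))])
    return labels, dwell


def total_distance(ts, lat, lon) -> float:
    """Sum of consecutive great-circle hops along the time-ordered track."""
    ts = np.asarray(ts, dtype=float)
    order = np.argsort(ts, kind="stable")
    lat = np.asarray(lat, dtype=float)[order]
    lon = np.asarray(lon, dtype=float)[order]
    if lat.size < 2:
        return 0.0 if lat.size == 1 else np.nan
    return float(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum())


def weighted_stationary_sd(ts, lat, lon,
                           speed_threshold: float = STATIONARY_SPEED_MS):
    """Dwell-time weighted SD of stationary latitude and longitude (degrees).

    A fix is stationary when the hop speed to the next fix is below
    ``speed_threshold``; its weight is the time to the next fix.  NaN when
    fewer than two stationary fixes exist.
    """
    ts = np.asarray(ts, dtype=float)
    order = np.argsort(ts, kind="stable")
    ts = ts[order]
    lat = np.asarray(lat, dtype=float)[order]
    lon = np.asarray(lon, dtype=float)[order]
    if ts.size < 2:
        return np.nan, np.nan
    dt = np.diff(ts)
    dist = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(dt > 0, dist / dt, np.inf)
    stat = speed < speed_threshold
    if stat.sum() < 2:
        return np.nan, np.nan
    w = dt[stat]
    if w.sum() <= 0:
        return np.nan, np.nan

    def wsd(x):
        mu = np.average(x, weights=w)
        return float(np.sqrt(np.average((x - mu) ** 2, weights=w)))

    return wsd(lat[:-1][stat]), wsd(lon[:-1][stat])


def classify_audio_frame(amplitude, cutpoints: dict | None = None):
    """Threshold amplitudes into silence / noise / voice / unknown."""
    cp = cutpoints or AUDIO_CUTPOINTS
    a = np.asarray(amplitude, dtype=float)
    if (a < 0).any():
        raise ValueError("amplitude must be >= 0")
    out = np.full(a.shape, "unknown", dtype=object)
    out[a < cp["voice"]] = "voice"
    out[a < cp["noise"]] = "noise"
    out[a < cp["silence"]] = "silence"
    if np.isscalar(amplitude):
        return str(out.item())
    return out


def noise_energy(amplitude) -> tuple[float, float]:
    """Mean and sample SD of per-frame energy (squared amplitude)."""
    a = np.asarray(amplitude, dtype=float)
    if a.size == 0:
        return np.nan, np.nan
    e = a ** 2
    sd = float(e.std(ddof=1)) if e.size > 1 else 0.0
    return float(e.mean()), sd


def device_use_features(screen_events: pd.DataFrame, window_start: int,
                        window_end: int | None = None) -> dict[str, float]:
    """Unlocked minutes and session-duration stats for one window.

    Sessions are unlocked->locked spans clipped to the window; the state at
    window start comes from the last event before it (locked if none), and
    an unlock still open at window end is clipped there.
    """
    if window_end is None:
        window_end = window_start + WINDOW_SEC
    ev = screen_events.sort_values("ts", kind="stable")
    before = ev[ev["ts"] <= window_start]
    state = before["state"].iloc[-1] if len(before) else "locked"
    inside = ev[(ev["ts"] > window_start) & (ev["ts"] < window_end)]
    sessions = []
    t = float(window_start)
    for _, row in inside.iterrows():
        if row["state"] == "locked" and state == "unlocked":
            sessions.append(float(row["ts"]) - t)
            state = "locked"
        elif row["state"] == "unlocked" and state == "locked":
            t = float(row["ts"])
            state = "unlocked"
    if state == "unlocked":
        sessions.append(float(window_end) - t)
    feats = {f"session_{s}": v for s, v in stat_block(sessions).items()} \
        if sessions else {f"session_{s}": np.nan for s in STAT_SUFFIXES}
    feats["unlock_minutes"] = float(sum(sessions)) / 60.0 if sessions else 0.0
    return feats


# ---------------------------------------------------------------------------
# per-window extraction
# ---------------------------------------------------------------------------

@dataclass
class MobileFeatureParams:
    cluster_distance_m: float = CLUSTER_DISTANCE_M
    stationary_speed_ms: float = STATIONARY_SPEED_MS
    audio_cutpoints: dict | None = None
    wifi_hash_buckets: int = WIFI_HASH_BUCKETS


GPS_FEATURES = ["radius_of_gyration", "time_at_cluster", "total_distance",
                "n_clusters", "wtsd_lat", "wtsd_lon"]

MOBILE_FEATURES = (
    GPS_FEATURES
    + [f"accel_{s}" for s in STAT_SUFFIXES]
    + [f"phone_angle_{s}" for s in STAT_SUFFIXES]
    + ["unlock_minutes"] + [f"session_{s}" for s in STAT_SUFFIXES]
    + ["audio_frac_silence", "audio_frac_noise", "audio_frac_voice",
       "audio_frac_unknown", "noise_energy_mean", "noise_energy_sd",
       "n_bluetooth", "top_wifi_ap", "light_avg", "light_max",
       "time_of_day", "day_of_week"]
)


def _wifi_bucket(ap_ids, n_buckets: int) -> float:
    import zlib
    ids = pd.Series(ap_ids).dropna()
    if ids.empty:
        return np.nan
    modal = ids.mode(dropna=True).iloc[0]
    return float(zlib.crc32(str(modal).encode()) % n_buckets)


def _grouped(df: pd.DataFrame, starts: np.ndarray) -> dict[int, pd.DataFrame]:
    """Split df by containing window, restricted to the requested starts."""
    if len(df) == 0:
        return {}
    w = window_floor(df["ts"].to_numpy())
    df = df.assign(_w=w)
    df = df[df["_w"].isin(starts)]
    return {int(k): g for k, g in df.groupby("_w", sort=True)}


def extract_mobile_features(pdata: ParticipantData, window_starts,
                            params: MobileFeatureParams | None = None
                            ) -> pd.DataFrame:
    """One row of smartphone features per requested window start."""
    params = params or MobileFeatureParams()
    starts = np.asarray(sorted(set(int(s) for s in window_starts)), dtype=np.int64)
    st = pdata.streams
    gps_g = _grouped(st.get("gps", pd.DataFrame()), starts)
    accel_g = _grouped(st.get("accel", pd.DataFrame()), starts)
    audio_g = _grouped(st.get("audio", pd.DataFrame()), starts)
    bt_g = _grouped(st.get("bluetooth", pd.DataFrame()), starts)
    wifi_g = _grouped(st.get("wifi", pd.DataFrame()), starts)
    light_g = _grouped(st.get("light", pd.DataFrame()), starts)
    screen = st.get("screen", pd.DataFrame(columns=["ts", "state"]))

    rows = []
    for s in starts:
        feats: dict[str, float] = {}
        g = gps_g.get(int(s))
        if g is not None and len(g):
            ts, lat, lon = (g["ts"].to_numpy(), g["lat"].to_numpy(),
                            g["lon"].to_numpy())
            feats["radius_of_gyration"] = radius_of_gyration(lat, lon)
            labels, dwell = location_clusters(
                ts, lat, lon, params.cluster_distance_m)
            feats["time_at_cluster"] = float(dwell.max())
            feats["n_clusters"] = float(dwell.size)
            feats["total_distance"] = total_distance(ts, lat, lon)
            feats["wtsd_lat"], feats["wtsd_lon"] = weighted_stationary_sd(
                ts, lat, lon, params.stationary_speed_ms)
        else:
            feats.update({k: np.nan for k in GPS_FEATURES})

        a = accel_g.get(int(s))
        if a is not None and len(a):
            mag = np.sqrt(a["ax"] ** 2 + a["ay"] ** 2 + a["az"] ** 2).to_numpy()
            norm = np.maximum(mag, 1e-9)
            angle = np.degrees(np.arccos(
                np.clip(np.abs(a["az"].to_numpy()) / norm, 0.0, 1.0)))
            feats.update({f"accel_{k}": v for k, v in stat_block(mag).items()})
            feats.update({f"phone_angle_{k}": v
                          for k, v in stat_block(angle).items()})
        else:
            feats.update({f"accel_{k}": np.nan for k in STAT_SUFFIXES})
            feats.update({f"phone_angle_{k}": np.nan for k in STAT_SUFFIXES})

        feats.update(device_use_features(screen, int(s)))

        au = audio_g.get(int(s))
        if au is not None and len(au):
            n = len(au)
            counts = au["inferred_class"].value_counts()
            for cls in ("silence", "noise", "voice", "unknown"):
                feats[f"audio_frac_{cls}"] = float(counts.get(cls, 0)) / n
            m, sd = noise_energy(au["amplitude"].to_numpy())
            feats["noise_energy_mean"], feats["noise_energy_sd"] = m, sd
        else:
            for cls in ("silence", "noise", "voice", "unknown"):
                feats[f"audio_frac_{cls}"] = np.nan
            feats["noise_energy_mean"] = feats["noise_energy_sd"] = np.nan

        b = bt_g.get(int(s))
        feats["n_bluetooth"] = (float(b["device_count"].mean())
                                if b is not None and len(b) else np.nan)
        w = wifi_g.get(int(s))
        feats["top_wifi_ap"] = (_wifi_bucket(w["ap_id"], params.wifi_hash_buckets)
                                if w is not None and len(w) else np.nan)
        li = light_g.get(int(s))
        if li is not None and len(li):
            feats["light_avg"] = float(li["lux"].mean())
            feats["light_max"] = float(li["lux"].max())
        else:
            feats["light_avg"] = feats["light_max"] = np.nan

        feats["time_of_day"] = float(int(local_hour(s, pdata.utc_offset_hours)))
        feats["day_of_week"] = float(day_of_week(s, pdata.utc_offset_hours))
        rows.append(feats)

    out = pd.DataFrame(rows, index=pd.Index(starts, name="window_start"))
    return out[MOBILE_FEATURES]
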