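"""Canonical in-memory data model and stream I/O.

All timestamps are integer (or float) POSIX epoch seconds in UTC. Each
participant carries a fixed UTC offset (no DST transitions), and every
"local" quantity — hour of day, day of week, calendar day — is derived by
shifting the epoch by that offset. Sensor windows are half-open 5-minute
intervals ``[start, start + 300)`` aligned to clock epochs, so a window's
identity is fully determined by its start timestamp.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("cannasense")
if not log.handlers:  # library default: quiet unless the app configures logging
    log.addHandler(logging.NullHandler())

WINDOW_SEC = 300
DAY_SEC = 86400
MINUTE_SEC = 60

#: Stream name -> required CSV columns.  ``reports`` and ``truth`` are kept
#: separate from the ten sensor streams.
STREAM_SCHEMAS: dict[str, list[str]] = {
    "gps": ["ts", "lat", "lon"],
    "accel": ["ts", "ax", "ay", "az"],
    "audio": ["ts", "amplitude", "inferred_class"],
    "screen": ["ts", "state"],
    "bluetooth": ["ts", "device_count"],
    "wifi": ["ts", "ap_id"],
    "light": ["ts", "lux"],
    "hr": ["ts", "bpm"],
    "steps": ["ts", "steps"],
    "sleep": ["night_date", "start_hour", "end_hour", "minutes_awake"],
}

REPORT_COLUMNS = [
    "report_id", "participant", "report_type", "report_time",
    "start_time", "end_time", "rating", "used_since_last",
    "hours_since_last_use",
]

TRUTH_COLUMNS = ["ts", "rating"]

FIXED_PROMPT_HOURS = (10, 15, 20)


# ---------------------------------------------------------------------------
# cohort containers
# ---------------------------------------------------------------------------

@dataclass
class ParticipantData:
    """All raw streams for one participant.

    ``truth`` is the hidden per-minute intoxication trace (0-10) used only by
    recovery tests; every downstream stage must run with ``truth=None``.
    """

    participant: str
    utc_offset_hours: float
    streams: dict[str, pd.DataFrame]
    reports: pd.DataFrame
    truth: pd.DataFrame | None = None

    def local_seconds(self, ts: np.ndarray) -> np.ndarray:
        return np.asarray(ts, dtype=float) + self.utc_offset_hours * 3600.0


@dataclass
class RawCohort:
    participants: dict[str, ParticipantData]

    def __iter__(self):
        return iter(self.participants.values())

    def drop_truth(self) -> "RawCohort":
        """Return a copy with the hidden truth traces removed (leakage guard)."""
        return RawCohort({
            pid: dataclasses.replace(p, truth=None)
            for pid, p in self.participants.items()
        })


# ---------------------------------------------------------------------------
# local-time helpers
# ---------------------------------------------------------------------------

def local_hour(ts, offset_hours: float) -> np.ndarray:
    """Clock hour (float, [0, 24)) at the participant's fixed UTC offset."""
    loc = np.asarray(ts, dtype=float) + offset_hours * 3600.0
    return (loc % DAY_SEC) / 3600.0


def local_day(ts, offset_hours: float) -> np.ndarray:
    """Local calendar-day index (days since the epoch, floor division)."""
    loc = np.asarray(ts, dtype=float) + offset_hours * 3600.0
    return np.floor(loc / DAY_SEC).astype(np.int64)


def day_of_week(ts, offset_hours: float) -> np.ndarray:
    """0=Monday .. 6=Sunday in local time (epoch day 0 was a Thursday)."""
    return ((local_day(ts, offset_hours) + 3) % 7).astype(np.int64)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """Half-open 5-minute window [start, end), start on a 300 s boundary."""

    participant: str
    start: int

    def __post_init__(self):
        if self.start % WINDOW_SEC != 0:
            raise ValueError(
                f"window start {self.start} not aligned to {WINDOW_SEC} s"
            )

    @property
    def end(self) -> int:
        return self.start + WINDOW_SEC


@dataclass
class StreamSlice:
    window: Window
    streams: dict[str, pd.DataFrame]


def window_floor(ts) -> np.ndarray:
    """Start of the window containing each timestamp (half-open convention:
    a sample exactly on a boundary belongs to the window starting there)."""
    return (np.floor(np.asarray(ts, dtype=float) / WINDOW_SEC) * WINDOW_SEC).astype(np.int64)


def observed_span(pdata: ParticipantData) -> tuple[int, int] | None:
    """(min, max) timestamp over all timestamped sensor streams, or None."""
    lo, hi = np.inf, -np.inf
    for name, df in pdata.streams.items():
        if "ts" not in df.columns or len(df) == 0:
            continue
        lo = min(lo, float(df["ts"].min()))
        hi = max(hi, float(df["ts"].max()))
    if not np.isfinite(lo):
        return None
    return int(lo), int(hi)


def align_windows(cohort: RawCohort, participant: str) -> list[Window]:
    """Tile the participant's observed period with aligned 5-minute windows.

    Returns every window touching [first sample, last sample]; an empty
    participant yields an empty list.
    """
    pdata = cohort.participants[participant]
    span = observed_span(pdata)
    if span is None:
        return []
    lo, hi = span
    first = int(window_floor(lo))
    last = int(window_floor(hi))  # window containing the last sample
    starts = range(first, last + WINDOW_SEC, WINDOW_SEC)
    return [Window(participant, s) for s in starts]


def slice_window(cohort: RawCohort, window: Window) -> StreamSlice:
    """All and only samples with ts in [start, end), stably ordered by ts."""
    pdata = cohort.participants[window.participant]
    out: dict[str, pd.DataFrame] = {}
    for name, df in pdata.streams.items():
        if "ts" not in df.columns:
            continue
        m = (df["ts"] >= window.start) & (df["ts"] < window.end)
        out[name] = df.loc[m].sort_values("ts", kind="stable").reset_index(drop=True)
    return StreamSlice(window, out)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """Raised when a stream CSV does not match its documented schema."""


def _check_schema(df: pd.DataFrame, columns: list[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {columns}"
        )


def write_cohort(cohort: RawCohort, directory: str | os.PathLike,
                 include_truth: bool = False) -> list[str]:
    """Write one CSV per stream per participant plus a reports CSV.

    The hidden truth trace is written only on request (it must never feed a
    downstream stage).  Returns the list of files written.
    """
    written = []
    root = os.fspath(directory)
    os.makedirs(root, exist_ok=True)
    meta = pd.DataFrame({
        "participant": list(cohort.participants),
        "utc_offset_hours": [p.utc_offset_hours for p in cohort],
    })
    meta_path = os.path.join(root, "participants.csv")
    meta.to_csv(meta_path, index=False)
    written.append(meta_path)
    for pid, pdata in cohort.participants.items():
        pdir = os.path.join(root, pid)
        os.makedirs(pdir, exist_ok=True)
        for name, columns in STREAM_SCHEMAS.items():
            path = os.path.join(pdir, f"{name}.csv")
            df = pdata.streams.get(name, pd.DataFrame(columns=columns))
            df.to_csv(path, index=False, columns=columns)
            written.append(path)
        rpath = os.path.join(pdir, "reports.csv")
        pdata.reports.to_csv(rpath, index=False, columns=REPORT_COLUMNS)
        written.append(rpath)
        if include_truth and pdata.truth is not None:
            tpath = os.path.join(pdir, "truth.csv")
            pdata.truth.to_csv(tpath, index=False, columns=TRUTH_COLUMNS)
            written.append(tpath)
    log.info("write_cohort: %d participants -> %d files",
             len(cohort.participants), len(written))
    return written


def _read_csv(path: str, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # surfaced with file context
        raise SchemaError(f"{path}: malformed CSV ({exc})") from exc
    _check_schema(df, columns, path)
    return df


def read_cohort(directory: str | os.PathLike) -> RawCohort:
    """Inverse of :func:`write_cohort` (up to timestamp serialization)."""
    root = os.fspath(directory)
    meta = _read_csv(os.path.join(root, "participants.csv"),
                     ["participant", "utc_offset_hours"])
    offsets = dict(zip(meta["participant"].astype(str),
                       meta["utc_offset_hours"].astype(float)))
    participants: dict[str, ParticipantData] = {}
    for pid in sorted(offsets):
        pdir = os.path.join(root, pid)
        streams = {}
        for name, columns in STREAM_SCHEMAS.items():
            streams[name] = _read_csv(os.path.join(pdir, f"{name}.csv"), columns)
        reports = _read_csv(os.path.join(pdir, "reports.csv"), REPORT_COLUMNS)
        truth = None
        tpath = os.path.join(pdir, "truth.csv")
        if os.path.exists(tpath):
            truth = _read_csv(tpath, TRUTH_COLUMNS)
        participants[pid] = ParticipantData(
            participant=pid,
            utc_offset_hours=offsets[pid],
            streams=streams,
            reports=reports,
            truth=truth,
        )
    return RawCohort(participants)
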