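"""Ground-truth labeling: reports -> validated episodes -> window labels.

Self-initiated use reports are filtered in a fixed rule order (missing
rating, exact duplicate, missing start/end or duration over 3 hours), each
rule's removals recorded in an audit.  Surviving reports become episodes
with two exclusion buffers: 30 minutes before the reported start (to absorb
reporting latency) and 3 hours after the reported end (residual effects).

Windows overlapping an episode take the episode's class — N for a rating
of 0, L for 1-3, MI for 4-10.  Windows overlapping any buffer, or
overlapping episodes of conflicting class, are flagged EXCLUDED.
Not-intoxicated windows are additionally sampled from "anchor" days:
local days holding a fixed-time survey where the participant answered
"no" to use-since-last-report and reported the last use strictly more
than 5 hours earlier, and on which no episode took place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    DAY_SEC, WINDOW_SEC, RawCohort, align_windows, local_day, log,
    window_floor,
)

MAX_EPISODE_MIN = 180
PRE_BUFFER_SEC = 30 * 60
POST_BUFFER_SEC = 3 * 3600
ANCHOR_MIN_HOURS = 5.0  # last use strictly more than this many hours ago

CLASS_ORDER = ("N", "L", "MI")

LABEL_COLUMNS = ["participant", "window_start", "label", "source_report_id"]


@dataclass(frozen=True)
class Episode:
    """A validated use episode with its exclusion buffers."""

    participant: str
    start: float
    end: float
    rating: int
    report_id: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("episode start must precede end")
        if self.duration_min > MAX_EPISODE_MIN:
            raise ValueError(
                f"episode duration {self.duration_min:.0f} min exceeds "
                f"{MAX_EPISODE_MIN} min")

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / 60.0

    @property
    def pre_buffer(self) -> tuple[float, float]:
        return (self.start - PRE_BUFFER_SEC, self.start)

    @property
    def post_buffer(self) -> tuple[float, float]:
        return (self.end, self.end + POST_BUFFER_SEC)

    @property
    def label(self) -> str:
        return map_rating_to_class(self.rating)


def map_rating_to_class(rating) -> str:
    """0 -> N, 1-3 -> L, 4-10 -> MI (total on the 0-10 scale)."""
    r = int(rating)
    if not 0 <= r <= 10:
        raise ValueError(f"rating {rating!r} outside 0-10")
    if r == 0:
        return "N"
    if r <= 3:
        return "L"
    return "MI"


def filter_reports(reports: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the report exclusion rules in order; return survivors + audit.

    Order: (1) drop reports without a rating; (2) drop exact duplicates on
    (participant, start, end, rating), keeping the first; (3) drop reports
    missing a start or end time or spanning more than 3 hours.
    """
    df = reports[reports["report_type"] == "self_initiated"].copy()
    audit = {"input": int(len(df))}

    has_rating = df["rating"].notna()
    audit["no_rating"] = int((~has_rating).sum())
    df = df[has_rating]

    dup = df.duplicated(subset=["participant", "start_time", "end_time",
                                "rating"], keep="first")
    audit["duplicate"] = int(dup.sum())
    df = df[~dup]

    dur_min = (df["end_time"] - df["start_time"]) / 60.0
    bad = (df["start_time"].isna() | df["end_time"].isna()
           | (dur_min > MAX_EPISODE_MIN) | (dur_min <= 0))
    audit["duration_or_missing_times"] = int(bad.sum())
    df = df[~bad]

    audit["kept"] = int(len(df))
    log.info("filter_reports: %s", audit)
    return df.reset_index(drop=True), audit


def episodes_from_reports(kept: pd.DataFrame) -> list[Episode]:
    return [
        Episode(participant=row.participant, start=float(row.start_time),
                end=float(row.end_time), rating=int(row.rating),
                report_id=str(row.report_id))
        for row in kept.itertuples()
    ]


def no_use_anchors(reports: pd.DataFrame) -> pd.DataFrame:
    """Fixed-time reports eligible to anchor not-intoxicated sampling."""
    df = reports[reports["report_type"] == "fixed_time"]
    m = ((df["used_since_last"] == "no")
         & (df["hours_since_last_use"] > ANCHOR_MIN_HOURS))
    return df.loc[m, ["report_id", "participant", "report_time"]].reset_index(drop=True)


def _interval_windows(lo: float, hi: float) -> range:
    """Starts of all windows overlapping the half-open interval [lo, hi)."""
    if hi <= lo:
        return range(0)
    first = int(window_floor(lo))
    last = int(window_floor(np.nextafter(hi, -np.inf)))
    return range(first, last + WINDOW_SEC, WINDOW_SEC)


def label_windows(cohort: RawCohort, episodes: list[Episode],
                  anchors: pd.DataFrame, seed: int = 0,
                  n_per_day: int = 24) -> tuple[pd.DataFrame, dict]:
    """Assign N / L / MI / EXCLUDED to windows; sample N from anchor days.

    Returns a table (participant, window_start, label, source_report_id) —
    EXCLUDED rows included for auditability — plus an audit of counts.
    """
    rng = np.random.default_rng(seed)
    audit = {"episode_windows": 0, "excluded_buffer": 0,
             "excluded_conflict": 0, "n_sampled": 0, "anchor_days": 0}
    rows = []
    for pid in sorted(cohort.participants):
        p_eps = [e for e in episodes if e.participant == pid]
        p_anchors = anchors[anchors["participant"] == pid]
        offset = cohort.participants[pid].utc_offset_hours
        windows = align_windows(cohort, pid)
        if not windows:
            continue
        starts = {w.start for w in windows}

        ep_hits: dict[int, list[Episode]] = {}
        buf_hits: dict[int, set[str]] = {}
        for ep in p_eps:
            for w in _interval_windows(ep.start, ep.end):
                ep_hits.setdefault(w, []).append(ep)
            for lo, hi in (ep.pre_buffer, ep.post_buffer):
                for w in _interval_windows(lo, hi):
                    buf_hits.setdefault(w, set()).add(ep.report_id)

        labeled: set[int] = set()
        for w, eps in sorted(ep_hits.items()):
            if w not in starts:
                continue
            labeled.add(w)
            classes = {e.label for e in eps}
            own = {e.report_id for e in eps}
            foreign_buffer = buf_hits.get(w, set()) - own
            if len(classes) > 1:
                rows.append((pid, w, "EXCLUDED", "conflict:" + ",".join(
                    sorted(own))))
                audit["excluded_conflict"] += 1
            elif foreign_buffer:
                rows.append((pid, w, "EXCLUDED", sorted(foreign_buffer)[0]))
                audit["excluded_buffer"] += 1
            else:
                rows.append((pid, w, eps[0].label, eps[0].report_id))
                audit["episode_windows"] += 1
        for w, owners in sorted(buf_hits.items()):
            if w in labeled or w not in starts:
                continue
            labeled.add(w)
            rows.append((pid, w, "EXCLUDED", sorted(owners)[0]))
            audit["excluded_buffer"] += 1

        # --- not-intoxicated sampling from anchor days -------------------
        ep_days: set[int] = set()
        for ep in p_eps:
            d0 = int(local_day(ep.start, offset))
            d1 = int(local_day(ep.end - 1, offset))
            ep_days.update(range(d0, d1 + 1))
        anchor_days: dict[int, str] = {}
        for row in p_anchors.itertuples():
            day = int(local_day(row.report_time, offset))
            if day not in ep_days:
                anchor_days.setdefault(day, str(row.report_id))
        audit["anchor_days"] += len(anchor_days)

        if anchor_days:
            all_starts = np.array(sorted(starts), dtype=np.int64)
            w_days = local_day(all_starts, offset)
            for day, anchor_id in sorted(anchor_days.items()):
                cand = all_starts[(w_days == day)]
                cand = np.array([w for w in cand if w not in labeled],
                                dtype=np.int64)
                if cand.size == 0:
                    continue
                take = min(n_per_day, cand.size)
                pick = rng.choice(cand, size=take, replace=False)
                for w in sorted(pick):
                    rows.append((pid, int(w), "N", anchor_id))
                audit["n_sampled"] += take

    labels = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    log.info("label_windows: %s", audit)
    return labels, audit


def down_sample_to_overlap(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Windows present in both coverage tables (participant, window_start)."""
    key = ["participant", "window_start"]
    return a.merge(b[key].drop_duplicates(), on=key, how="inner")


def label_cohort(cohort: RawCohort, seed: int = 0, n_per_day: int = 24
                 ) -> tuple[pd.DataFrame, dict]:
    """Full labeling pass over a cohort's reports."""
    reports = pd.concat([p.reports for p in cohort], ignore_index=True)
    kept, report_audit = filter_reports(reports)
    episodes = episodes_from_reports(kept)
    anchors = no_use_anchors(reports)
    labels, label_audit = label_windows(cohort, episodes, anchors, seed=seed,
                                        n_per_day=n_per_day)
    return labels, {"reports": report_audit, "windows": label_audit}
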