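"""Reading, typing and gridding of sparse minute-level sleep observations.

The sensor emits one record per minute while the bed is occupied. This module
localizes timestamps to the participant's time zone, validates fields, places
observations on noon-to-noon occupancy grids (one cell per wall-clock minute),
and detects bed-occupancy transitions as maximal runs of occupied minutes.

Conventions: all intervals are half-open ``[start, end)``; a minute belongs to
the period in which it starts; occupancy is defined by record presence, so a
minute with missing heart/respiration values still counts as occupied. Grids
are indexed by local wall-clock minutes, hence always 1440 cells — on the
autumn daylight-saving transition the repeated hour collapses (keep-first).
"""

from __future__ import annotations

import datetime as dt
import zoneinfo
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import STATES

MINUTES_PER_DAY = 1440

REQUIRED_COLUMNS = ["participant_id", "timestamp", "heart_rate",
                    "respiration_rate", "snoring", "state"]


@dataclass(frozen=True)
class OccupancyGrid:
    """Binary per-minute bed occupancy over one noon-to-noon local window."""

    participant_id: str
    window_start: dt.datetime  # local noon, naive wall clock
    occupied: np.ndarray  # uint8 vector of length 1440

    def __post_init__(self):
        if len(self.occupied) != MINUTES_PER_DAY:
            raise ValueError("occupancy grid must have exactly 1440 cells")

    @property
    def night_date(self) -> dt.date:
        return self.window_start.date()


@dataclass(frozen=True)
class BedPeriod:
    """Maximal run of occupied minutes, half-open [start, end)."""

    start: dt.datetime
    end: dt.datetime

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("BedPeriod end must be after start")

    @property
    def minutes(self) -> int:
        return int((self.end - self.start).total_seconds() // 60)


def localize_and_type(raw: pd.DataFrame, zone: str):
    """Validate and localize raw rows; returns (observations, diagnostics).

    Timestamps are parsed (UTC/offset-aware converted into ``zone``; naive
    values taken as already-local) and truncated to the minute. Rows with an
    unparseable timestamp, an out-of-range physiology value, or an unknown
    sleep-state code are rejected, one diagnostic string per row. Duplicate
    (participant, timestamp) pairs keep the first occurrence.
    """
    tz = zoneinfo.ZoneInfo(zone)  # raises for unknown zone names
    df = raw.copy()
    diagnostics: list[str] = []

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=False, format="mixed")
    bad = ts.isna()

    def _to_local(t):
        if pd.isna(t):
            return pd.NaT
        if t.tzinfo is None:
            return t.replace(second=0, microsecond=0)
        return t.tz_convert(tz).tz_localize(None).replace(second=0, microsecond=0)

    # mixed aware/naive inputs: coerce elementwise
    if ts.dt.tz is not None:
        local = ts.dt.tz_convert(tz).dt.tz_localize(None).dt.floor("min")
    else:
        local = pd.Series([_to_local(t) for t in ts], index=df.index)
    for i in df.index[bad]:
        diagnostics.append(f"row {i}: unparseable timestamp {raw.loc[i, 'timestamp']!r}")

    hr = pd.to_numeric(df["heart_rate"], errors="coerce")
    rr = pd.to_numeric(df["respiration_rate"], errors="coerce")
    bad_hr = hr.notna() & ~hr.between(0, 300, inclusive="neither")
    bad_rr = rr.notna() & ~rr.between(0, 100, inclusive="neither")
    for i in df.index[bad_hr]:
        diagnostics.append(f"row {i}: heart_rate out of range: {df.loc[i, 'heart_rate']!r}")
    for i in df.index[bad_rr]:
        diagnostics.append(f"row {i}: respiration_rate out of range: {df.loc[i, 'respiration_rate']!r}")

    state = df["state"].astype("string")
    bad_state = state.notna() & ~state.isin(STATES)
    for i in df.index[bad_state]:
        diagnostics.append(f"row {i}: state not one of {STATES}: {df.loc[i, 'state']!r}")

    keep = ~(bad | bad_hr | bad_rr | bad_state)
    out = pd.DataFrame(
        {
            "participant_id": df.loc[keep, "participant_id"].astype(str),
            "timestamp": local[keep],
            "heart_rate": hr[keep],
            "respiration_rate": rr[keep],
            "snoring": pd.to_numeric(df.loc[keep, "snoring"], errors="coerce")
            .fillna(0).astype(int).astype(bool),
            "state": state[keep],
        }
    ).sort_values(["participant_id", "timestamp"], kind="mergesort")
    n_dup = int(out.duplicated(["participant_id", "timestamp"]).sum())
    if n_dup:
        diagnostics.append(f"dropped {n_dup} duplicate (participant, timestamp) rows (kept first)")
        out = out.drop_duplicates(["participant_id", "timestamp"], keep="first")
    return out.reset_index(drop=True), diagnostics


def _window_start(ts: pd.Timestamp) -> dt.datetime:
    shifted = ts - pd.Timedelta(hours=12)
    return dt.datetime.combine(shifted.date(), dt.time(12, 0))


def resample_occupancy(observations: pd.DataFrame) -> list[OccupancyGrid]:
    """One grid per noon-to-noon window holding >= 1 observation.

    A cell is 1 iff an observation exists for that wall-clock minute; total
    occupied cells across grids equals the number of distinct observation
    minutes (conservation).
    """
    grids: list[OccupancyGrid] = []
    if observations.empty:
        return grids
    df = observations.sort_values(["participant_id", "timestamp"], kind="mergesort")
    starts = df["timestamp"].map(_window_start)
    for (pid, w0), sub in df.groupby([df["participant_id"], starts], sort=True):
        occ = np.zeros(MINUTES_PER_DAY, dtype=np.uint8)
        idx = ((sub["timestamp"] - pd.Timestamp(w0)).dt.total_seconds() // 60).astype(int)
        occ[idx.to_numpy()] = 1
        grids.append(OccupancyGrid(str(pid), w0, occ))
    return grids


def detect_transitions(grid: OccupancyGrid) -> list[BedPeriod]:
    """Maximal runs of occupied minutes, in time order."""
    occ = np.asarray(grid.occupied, dtype=np.int8)
    if occ.sum() == 0:
        return []
    edges = np.diff(np.concatenate(([0], occ, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        BedPeriod(
            grid.window_start + dt.timedelta(minutes=int(s)),
            grid.window_start + dt.timedelta(minutes=int(e)),
        )
        for s, e in zip(starts, ends)
    ]


def read_minutes(path: str) -> pd.DataFrame:
    """Read the minute CSV/Parquet schema."""
    if str(path).endswith((".parquet", ".pq")):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_minutes(df: pd.DataFrame, path: str) -> None:
    if str(path).endswith((".parquet", ".pq")):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
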