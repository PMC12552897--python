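"""Nightly sleep metrics from clustered bed-occupancy periods.

Bed periods are merged into episodes when separated by < 30 minutes, labelled
diurnal (starting 08:00-20:00 and ending the same calendar day) or nocturnal,
and each nocturnal episode is summarized into the standard nightly metric set:

========  ==================================================================
TO_BED    going-to-bed clock time as an angle from midday (15 deg/hour)
ARISE     wake-up clock time as an angle from midnight
NOP       nocturnal occupancy period: first-to-last observed minute,
          inclusive span, hours
IBT/OBT   in-bed time (observed minutes / 60) and out-of-bed time (NOP - IBT)
IBP       IBT / NOP
EXITS     count of gaps >= 2 min between consecutive observation minutes
EXIT_DUR  OBT * 60 / EXITS (0 when EXITS = 0), minutes
*_DUR     hours per sleep state (DEEP/AWAKE/REM/LIGHT)
WSA_*     state duration / IBT
SNT/SNR   snoring minutes and their proportion of in-bed minutes
HR, RR    nightly mean heart / respiration rate over minutes where present
========  ==================================================================

The night date is the maximum observation timestamp minus 12 hours. Episodes
spanning more than 24 hours of occupancy are excluded before metrics.

Quality filtering removes nights with invalid or extreme values: > 20 exits,
in-bed proportion outside [0.6, 1.0], heart rate outside [45, 85] bpm,
respiration rate outside [10, 25] cpm, mean exit duration > 60 min,
out-of-bed time >= 180 min, in-bed time outside [4, 16] h, going to bed
before 17:20 or after 03:00 (wrapped across midnight), or waking before
02:40 or after 23:45. All ranges are inclusive except out-of-bed time
(strict).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import BedPeriod, OccupancyGrid, detect_transitions, localize_and_type, resample_occupancy

METRIC_COLUMNS = [
    "TO_BED", "ARISE", "NOP", "IBT", "IBP", "OBT", "EXITS", "EXIT_DUR",
    "DEEP_DUR", "AWAKE_DUR", "REM_DUR", "LIGHT_DUR", "SNT",
    "WSA_DEEP", "WSA_AWAKE", "WSA_REM", "WSA_LIGHT", "HR", "RR", "SNR",
]

CLUSTER_GAP_MINUTES = 30


@dataclass
class BedCluster:
    periods: list  # ordered BedPeriods, consecutive gaps < 30 min
    classification: str | None = None  # "diurnal" | "nocturnal"

    @property
    def start(self) -> dt.datetime:
        return self.periods[0].start

    @property
    def end(self) -> dt.datetime:
        return self.periods[-1].end


@dataclass(frozen=True)
class FilterVerdict:
    night: tuple  # (participant_id, night_date)
    kept: bool
    violated_rules: tuple

    def __post_init__(self):
        if self.kept != (len(self.violated_rules) == 0):
            raise ValueError("kept must hold exactly when no rule is violated")


def cluster_periods(periods: list) -> list[BedCluster]:
    """Greedy merge of time-ordered bed periods with gaps < 30 minutes."""
    clusters: list[BedCluster] = []
    for p in periods:
        if clusters and (p.start - clusters[-1].end) < dt.timedelta(minutes=CLUSTER_GAP_MINUTES):
            clusters[-1].periods.append(p)
        else:
            clusters.append(BedCluster([p]))
    return clusters


def classify_cluster(cluster: BedCluster) -> str:
    """Diurnal iff the episode starts in [08:00, 20:00) and its last occupied
    minute falls on the same calendar day; otherwise nocturnal."""
    if not cluster.periods:
        raise ValueError("cannot classify an empty cluster")
    start = cluster.start
    last_minute = cluster.end - dt.timedelta(minutes=1)
    if dt.time(8, 0) <= start.time() < dt.time(20, 0) and last_minute.date() == start.date():
        return "diurnal"
    return "nocturnal"


def clock_angle(t: dt.time, origin: str = "midday") -> float:
    """Clock time in degrees (15 deg/hour) from the requested origin.

    Midday origin: hours before 12:00 wrap to h + 24, so 03:00 -> 225 deg.
    Midnight origin: plain h + m/60 scaled, so 23:45 -> 356.25 deg.
    """
    h, m = t.hour, t.minute + t.second / 60
    if origin == "midday":
        h = h + 24 if h < 12 else h
        return 15.0 * ((h - 12) + m / 60)
    if origin == "midnight":
        return 15.0 * (h + m / 60)
    raise ValueError("origin must be 'midday' or 'midnight'")


def compute_night_metrics(observations: pd.DataFrame) -> dict:
    """Nightly metric record from one nocturnal episode's observations.

    ``observations`` holds the episode's minute rows (timestamp, heart_rate,
    respiration_rate, snoring, state). Raises on an empty episode or one
    whose occupancy spans more than 24 hours.
    """
    if observations.empty:
        raise ValueError("cannot compute metrics for an episode with zero observations")
    ts = pd.to_datetime(observations["timestamp"]).sort_values().reset_index(drop=True)
    k = len(ts)
    t0, t1 = ts.iloc[0], ts.iloc[-1]
    nop_minutes = (t1 - t0).total_seconds() / 60 + 1  # inclusive span
    if nop_minutes > 24 * 60:
        raise ValueError("episode occupancy exceeds 24 hours; outside analysis scope")
    gaps = ts.diff().dt.total_seconds().div(60).iloc[1:]
    exits = int((gaps >= 2).sum())

    nop = nop_minutes / 60
    ibt = k / 60
    obt = nop - ibt
    exit_dur = (obt * 60 / exits) if exits else 0.0

    state = observations["state"]
    dur = {s: float((state == s).sum()) / 60 for s in ("DEEP", "AWAKE", "REM", "LIGHT")}
    hr = pd.to_numeric(observations["heart_rate"], errors="coerce")
    rr = pd.to_numeric(observations["respiration_rate"], errors="coerce")
    snt = float(pd.to_numeric(observations["snoring"], errors="coerce").fillna(0).astype(bool).sum())

    return {
        "night_date": (t1 - pd.Timedelta(hours=12)).date(),
        "to_bed": t0.time(),
        "wake_up": t1.time(),
        "TO_BED": clock_angle(t0.time(), "midday"),
        "ARISE": clock_angle(t1.time(), "midnight"),
        "NOP": nop,
        "IBT": ibt,
        "IBP": ibt / nop,
        "OBT": obt,
        "EXITS": exits,
        "EXIT_DUR": exit_dur,
        "DEEP_DUR": dur["DEEP"],
        "AWAKE_DUR": dur["AWAKE"],
        "REM_DUR": dur["REM"],
        "LIGHT_DUR": dur["LIGHT"],
        "SNT": snt,
        "WSA_DEEP": dur["DEEP"] / ibt,
        "WSA_AWAKE": dur["AWAKE"] / ibt,
        "WSA_REM": dur["REM"] / ibt,
        "WSA_LIGHT": dur["LIGHT"] / ibt,
        "HR": float(hr.mean()) if hr.notna().any() else np.nan,
        "RR": float(rr.mean()) if rr.notna().any() else np.nan,
        "SNR": snt / k,
    }


# ---------------------------------------------------------------------------
# quality filters


def _time_in_wrapped_range(t: dt.time, lo: dt.time, hi: dt.time) -> bool:
    """Inclusive membership in a clock range that may wrap past midnight."""
    if lo <= hi:
        return lo <= t <= hi
    return t >= lo or t <= hi


@dataclass(frozen=True)
class QualityRules:
    exits_max: int = 20
    ibp_range: tuple = (0.6, 1.0)
    hr_range: tuple = (45.0, 85.0)
    rr_range: tuple = (10.0, 25.0)
    exit_dur_max: float = 60.0
    obt_max_hours: float = 3.0  # strict
    ibt_range: tuple = (4.0, 16.0)
    to_bed_window: tuple = field(default_factory=lambda: (dt.time(17, 20), dt.time(3, 0)))
    wake_up_window: tuple = field(default_factory=lambda: (dt.time(2, 40), dt.time(23, 45)))


DEFAULT_RULES = QualityRules()


def apply_quality_filters(record: dict | pd.Series,
                          rules: QualityRules = DEFAULT_RULES) -> FilterVerdict:
    """Pure predicate over one night record; every violated rule is listed."""
    r = record
    violated = []
    required = ["EXITS", "IBP", "HR", "RR", "EXIT_DUR", "OBT", "IBT"]
    if any(pd.isna(r[c]) for c in required):
        violated.append("missing_value")
    else:
        if r["EXITS"] > rules.exits_max:
            violated.append("exits_max")
        if not rules.ibp_range[0] <= r["IBP"] <= rules.ibp_range[1]:
            violated.append("ibp_range")
        if not rules.hr_range[0] <= r["HR"] <= rules.hr_range[1]:
            violated.append("hr_range")
        if not rules.rr_range[0] <= r["RR"] <= rules.rr_range[1]:
            violated.append("rr_range")
        if r["EXIT_DUR"] > rules.exit_dur_max:
            violated.append("exit_dur_max")
        if r["OBT"] >= rules.obt_max_hours:
            violated.append("obt_max")
        if not rules.ibt_range[0] <= r["IBT"] <= rules.ibt_range[1]:
            violated.append("ibt_range")
        if not _time_in_wrapped_range(r["to_bed"], *rules.to_bed_window):
            violated.append("to_bed_window")
        if not _time_in_wrapped_range(r["wake_up"], *rules.wake_up_window):
            violated.append("wake_up_window")
    night = (r.get("participant_id", ""), r.get("night_date"))
    return FilterVerdict(night, kept=not violated, violated_rules=tuple(violated))


# ---------------------------------------------------------------------------
# pipeline convenience


def nights_from_grids(grids: list[OccupancyGrid],
                      observations: pd.DataFrame) -> pd.DataFrame:
    """Nightly metric table for every nocturnal episode found in ``grids``.

    Episodes are rebuilt per participant across windows (periods can abut a
    window edge), then metrics are computed from the member observations.
    """
    obs = observations.sort_values(["participant_id", "timestamp"], kind="mergesort")
    obs_by_pid = dict(tuple(obs.groupby("participant_id", sort=True)))
    rows = []
    by_pid: dict[str, list] = {}
    for g in grids:
        by_pid.setdefault(g.participant_id, []).extend(detect_transitions(g))
    for pid, periods in by_pid.items():
        periods.sort(key=lambda p: p.start)
        sub = obs_by_pid.get(pid)
        if sub is None:
            continue
        ts = pd.to_datetime(sub["timestamp"])
        for cluster in cluster_periods(periods):
            cluster.classification = classify_cluster(cluster)
            if cluster.classification != "nocturnal":
                continue
            member = sub[(ts >= pd.Timestamp(cluster.start)) & (ts < pd.Timestamp(cluster.end))]
            # episode may contain internal exits >= 30 min? no: clusters merge
            # only gaps < 30 min, but the >= 2 min gap rule applies inside.
            if member.empty:
                continue
            try:
                rec = compute_night_metrics(member)
            except ValueError:
                continue  # > 24 h episodes are out of scope
            rec["participant_id"] = pid
            rows.append(rec)
    cols = ["participant_id", "night_date", "to_bed", "wake_up"] + METRIC_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def nights_from_minutes(minute_table: pd.DataFrame, zone: str = "UTC") -> pd.DataFrame:
    """Minute observations -> localized -> gridded -> nightly metric table."""
    obs, _ = localize_and_type(minute_table, zone)
    grids = resample_occupancy(obs)
    return nights_from_grids(grids, obs)


def filter_nights(nights: pd.DataFrame,
                  rules: QualityRules = DEFAULT_RULES):
    """Split a nightly metric table into (kept, drop report).

    The report has one row per dropped night with a ``violated_rules`` column
    (semicolon-joined rule identifiers).
    """
    verdicts = [apply_quality_filters(row, rules) for _, row in nights.iterrows()]
    kept_mask = np.array([v.kept for v in verdicts], dtype=bool)
    report = nights.loc[~kept_mask, ["participant_id", "night_date"]].copy()
    report["violated_rules"] = [
        ";".join(v.violated_rules) for v, keep in zip(verdicts, kept_mask) if not keep
    ]
    return nights.loc[kept_mask].reset_index(drop=True), report.reset_index(drop=True)
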