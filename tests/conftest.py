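"""Shared fixtures: hand-constructed nights and small synthetic cohorts."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from drisleep import synthetic_cohort as sc


def minute_range(start: dt.datetime, end: dt.datetime, **fields) -> pd.DataFrame:
    """Minute observations covering [start, end] inclusive, constant fields."""
    ts = pd.date_range(start, end, freq="min")
    base = {"heart_rate": 60.0, "respiration_rate": 15.0, "snoring": 0, "state": "LIGHT"}
    base.update(fields)
    return pd.DataFrame({"timestamp": ts, **base})


@pytest.fixture
def worked_night() -> pd.DataFrame:
    """The hand-worked night: in bed 22:00-06:59 with one 9-minute exit.

    Observations every minute 22:00-01:59 and 02:09-06:59 (absent
    02:00-02:08), so the inclusive span is 540 min, 531 observed.
    """
    a = minute_range(dt.datetime(2021, 6, 1, 22, 0), dt.datetime(2021, 6, 2, 1, 59))
    b = minute_range(dt.datetime(2021, 6, 2, 2, 9), dt.datetime(2021, 6, 2, 6, 59))
    df = pd.concat([a, b], ignore_index=True)
    df.insert(0, "participant_id", "P-001")
    return df


def _night_record(**overrides) -> dict:
    """A quality-compliant nightly metric record; override fields to violate
    exactly one filter rule."""
    rec = {
        "participant_id": "P-001", "night_date": dt.date(2021, 6, 1),
        "to_bed": dt.time(22, 30), "wake_up": dt.time(7, 0),
        "NOP": 8.5, "IBT": 8.0, "IBP": 8.0 / 8.5, "OBT": 0.5,
        "EXITS": 3, "EXIT_DUR": 10.0, "HR": 62.0, "RR": 15.0,
    }
    rec.update(overrides)
    return rec


@pytest.fixture
def filter_fixture() -> pd.DataFrame:
    """12 nights: one violation each for 9 rules + 3 compliant nights."""
    rows = [
        # one targeted violation per rule, all other rules satisfied
        ("exits_max", _night_record(EXITS=21, EXIT_DUR=0.5 * 60 / 21)),
        ("ibp_range", _night_record(to_bed=dt.time(23, 0), wake_up=dt.time(6, 0),
                                    NOP=7.0, IBT=4.1, OBT=2.9, IBP=4.1 / 7.0,
                                    EXITS=4, EXIT_DUR=2.9 * 60 / 4)),
        ("hr_range", _night_record(HR=90.0)),
        ("rr_range", _night_record(RR=30.0)),
        ("exit_dur_max", _night_record(EXITS=2, OBT=2.34, EXIT_DUR=70.0,
                                       wake_up=dt.time(9, 0),
                                       NOP=10.5, IBT=8.16, IBP=8.16 / 10.5)),
        ("obt_max", _night_record(NOP=12.0, IBT=8.8, OBT=3.2, IBP=8.8 / 12.0,
                                  wake_up=dt.time(10, 30),
                                  EXITS=10, EXIT_DUR=19.2)),
        ("ibt_range", _night_record(to_bed=dt.time(23, 30), wake_up=dt.time(4, 30),
                                    NOP=5.0, IBT=3.5, OBT=1.5, IBP=0.7,
                                    EXITS=3, EXIT_DUR=30.0)),
        ("to_bed_window", _night_record(to_bed=dt.time(4, 0), wake_up=dt.time(12, 0),
                                        NOP=8.0, IBT=7.5, OBT=0.5, IBP=7.5 / 8.0)),
        ("wake_up_window", _night_record(to_bed=dt.time(18, 0), wake_up=dt.time(2, 0),
                                         NOP=8.0, IBT=7.5, OBT=0.5, IBP=7.5 / 8.0)),
        (None, _night_record()),
        (None, _night_record(EXITS=20, EXIT_DUR=1.5)),  # inclusive boundary
        (None, _night_record(to_bed=dt.time(17, 20), wake_up=dt.time(2, 40),
                             NOP=9.33, IBT=9.0, OBT=0.33, IBP=9.0 / 9.33)),
    ]
    df = pd.DataFrame([r for _, r in rows])
    df["expected_rule"] = [r for r, _ in rows]
    df["night_date"] = [dt.date(2021, 6, 1) + dt.timedelta(days=i) for i in range(len(df))]
    return df


@pytest.fixture(scope="session")
def phenotype_nights():
    """600 minute-level nights from the 3 planted phenotypes, gridded."""
    from drisleep import ingest
    from drisleep._rng import child_rng
    from drisleep import phenotype_clustering as pc

    frames = []
    for name, prof in sc.phenotype_profiles().items():
        for j in range(200):
            obs = sc.generate_night(
                prof, dt.date(2021, 1, 1) + dt.timedelta(days=j % 300),
                child_rng(7, name, j))
            obs.insert(0, "participant_id", f"{name}-{j % 20:02d}")
            frames.append(obs)
    obs, _ = ingest.localize_and_type(pd.concat(frames, ignore_index=True), "UTC")
    grids = ingest.resample_occupancy(obs)
    aggs = [pc.aggregate_15min(g) for g in grids]
    truth = [a.night[0].rsplit("-", 1)[0] for a in aggs]
    return aggs, truth


@pytest.fixture(scope="session")
def dri_signal_cohort() -> pd.DataFrame:
    """AD-like vs older-control cohort, 40+400 participants x 180 nights."""
    nights = sc.cohort_night_records(
        [("AD", 40, 180, sc.profile_alzheimers()),
         ("POP", 400, 180, sc.profile_older_control())],
        seed=1,
    )
    nights["is_case"] = (nights["group"] == "AD").astype(int)
    return nights
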