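"""Synthetic cohort generator for under-mattress sleep-sensor studies.

Real minute-level recordings from contactless bed sensors are rarely shareable,
so every downstream stage of this package is exercised against a generator that
emulates their structure: per participant-night, a sparse stream of one-minute
observations (timestamp, heart rate, respiration rate, snore flag, 4-level
sleep state) present only while the bed is occupied, plus periodic clinical
assessment scores (ADAS-Cog, NPI, BADL, PSQI).

The generative model, per night:

* going-to-bed and arising clock times are Gaussian around profile means
  (defaults follow published group descriptives for Alzheimer's-disease and
  general-population cohorts, e.g. to-bed 22:47 +/- 2.8 h for the AD group);
* bed exits: a Poisson count of exits with log-normal durations, placed
  uniformly inside the in-bed interval (heavy-tailed durations match the
  printed 9.6 +/- 23.9 min scale);
* one optional diurnal nap block;
* sleep states follow a first-order Markov chain at 1-minute resolution
  starting in LIGHT; awake minutes stay in bed (observations), distinct from
  exits (absent minutes);
* heart/respiration rate are i.i.d. Gaussian around nightly means; snoring is
  a per-minute Bernoulli flag whose per-night propensity is beta-distributed
  around the profile mean (snoring varies night to night, not just minute to
  minute).

A per-participant latent "disturbance" scalar jointly modulates sleep timing,
bed exits and clinical scale scores, so association-stage recovery tests have
a planted ground truth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import as_rng, child_rng

STATES = ("AWAKE", "LIGHT", "DEEP", "REM")

#: canonical column order of the minute-observation schema shared with ingest
MINUTE_COLUMNS = [
    "participant_id",
    "timestamp",
    "heart_rate",
    "respiration_rate",
    "snoring",
    "state",
]

SCALES = ("ADAS-Cog", "NPI", "BADL", "PSQI")


def hours_since_noon(t: dt.time) -> float:
    """Clock time mapped to hours elapsed since the preceding noon, in [0, 24)."""
    return ((t.hour - 12) % 24) + t.minute / 60 + t.second / 3600


def _time_from_hsn(h: float) -> dt.time:
    total = int(round(((h + 12) % 24) * 60)) % 1440
    return dt.time(total // 60, total % 60)


def transition_from_stationary(pi, persistence: float = 0.85) -> np.ndarray:
    """Row-stochastic 4x4 chain with stationary distribution ``pi``.

    Rows are ``persistence * e_i + (1 - persistence) * pi``; the stationary
    law of that mixture is exactly ``pi``.
    """
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    return persistence * np.eye(len(pi)) + (1 - persistence) * pi[None, :]


@dataclass(frozen=True)
class NightProfile:
    """Distributional parameters for one group's nights."""

    to_bed_mean: dt.time
    to_bed_sd: float  # hours
    arise_mean: dt.time
    arise_sd: float  # hours
    exit_rate: float  # expected exits/night (Poisson mean)
    exit_dur_mean: float  # minutes (log-normal mean)
    nap_prob: float
    hr_mean: float
    hr_sd: float
    rr_mean: float
    rr_sd: float
    snore_prob: float
    state_transition: np.ndarray = field(
        default_factory=lambda: transition_from_stationary([0.15, 0.55, 0.2, 0.1])
    )

    def __post_init__(self):
        for name in ("to_bed_sd", "arise_sd", "hr_sd", "rr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nap_prob", "snore_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.exit_rate < 0 or self.exit_dur_mean < 0:
            raise ValueError("exit_rate and exit_dur_mean must be >= 0")
        P = np.asarray(self.state_transition, dtype=float)
        if P.shape != (4, 4) or np.any(P < 0):
            raise ValueError("state_transition must be a nonnegative 4x4 matrix")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("state_transition rows must each sum to 1")
        if hours_since_noon(self.arise_mean) <= hours_since_noon(self.to_bed_mean):
            raise ValueError("arise_mean must fall after to_bed_mean within the noon-to-noon night")
        object.__setattr__(self, "state_transition", P)

    @property
    def stationary_states(self) -> np.ndarray:
        """Stationary distribution of the sleep-state chain."""
        P = self.state_transition
        vals, vecs = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(vals - 1)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


def profile_alzheimers() -> NightProfile:
    """AD-group descriptives: early to-bed, late arise, frequent/long exits."""
    return NightProfile(
        to_bed_mean=dt.time(22, 47), to_bed_sd=2.8,
        arise_mean=dt.time(8, 29), arise_sd=2.4,
        exit_rate=3.5, exit_dur_mean=9.6, nap_prob=0.25,
        hr_mean=62.0, hr_sd=5.0, rr_mean=15.0, rr_sd=2.0,
        snore_prob=0.03,
        state_transition=transition_from_stationary([0.223, 0.532, 0.155, 0.090]),
    )


def profile_older_control() -> NightProfile:
    """Age/sex-matched older general-population descriptives."""
    return NightProfile(
        to_bed_mean=dt.time(22, 44), to_bed_sd=2.2,
        arise_mean=dt.time(7, 52), arise_sd=2.5,
        exit_rate=3.1, exit_dur_mean=8.7, nap_prob=0.10,
        hr_mean=62.0, hr_sd=5.0, rr_mean=15.0, rr_sd=2.0,
        snore_prob=0.08,
        state_transition=transition_from_stationary([0.140, 0.496, 0.234, 0.130]),
    )


def profile_young() -> NightProfile:
    """18-40 age band: late to-bed, few short exits, more REM."""
    return NightProfile(
        to_bed_mean=dt.time(23, 59), to_bed_sd=1.9,
        arise_mean=dt.time(8, 50), arise_sd=2.1,
        exit_rate=2.3, exit_dur_mean=4.3, nap_prob=0.02,
        hr_mean=62.0, hr_sd=5.0, rr_mean=15.0, rr_sd=2.0,
        snore_prob=0.02,
        state_transition=transition_from_stationary([0.114, 0.529, 0.180, 0.177]),
    )


def phenotype_profiles() -> dict[str, NightProfile]:
    """Three well-separated night phenotypes for planted-cluster benchmarks.

    Mean timing/duration regimes follow published night-cluster exemplars:
    very early fragmented (to-bed 19:30, long in-bed time, many exits),
    prolonged (23:00 -> 09:03), normative (00:05 -> 07:04, short). Night-to-
    night timing SDs are set to about half the spread observed for discovered
    clusters: an observed cluster's spread includes boundary nights, whereas
    a planted benchmark needs classes that are separable by construction.
    """
    return {
        "early_fragmented": NightProfile(
            to_bed_mean=dt.time(19, 30), to_bed_sd=0.45,
            arise_mean=dt.time(7, 50), arise_sd=0.5,
            exit_rate=6.0, exit_dur_mean=15.0, nap_prob=0.0,
            hr_mean=62, hr_sd=5, rr_mean=15, rr_sd=2, snore_prob=0.03,
        ),
        "prolonged": NightProfile(
            to_bed_mean=dt.time(23, 0), to_bed_sd=0.35,
            arise_mean=dt.time(9, 3), arise_sd=0.3,
            exit_rate=2.0, exit_dur_mean=8.0, nap_prob=0.0,
            hr_mean=62, hr_sd=5, rr_mean=15, rr_sd=2, snore_prob=0.05,
        ),
        "normative": NightProfile(
            to_bed_mean=dt.time(0, 5), to_bed_sd=0.35,
            arise_mean=dt.time(7, 4), arise_sd=0.3,
            exit_rate=1.0, exit_dur_mean=5.0, nap_prob=0.0,
            hr_mean=62, hr_sd=5, rr_mean=15, rr_sd=2, snore_prob=0.05,
        ),
    }


def perturb_profile(profile: NightProfile, z: float,
                    timing_shift: float = 0.15,
                    exit_log_scale: float = 0.25) -> NightProfile:
    """Apply a participant's latent disturbance ``z`` to a group profile.

    Positive ``z`` moves to-bed earlier and arise later by ``timing_shift * z``
    hours each (lengthening time in bed) and scales the exit rate and mean
    exit duration multiplicatively on the log scale.
    """
    tb = hours_since_noon(profile.to_bed_mean) - timing_shift * z
    ar = hours_since_noon(profile.arise_mean) + timing_shift * z
    tb = float(np.clip(tb, 0.5, 23.0))
    ar = float(np.clip(ar, tb + 1.0, 23.9))
    return replace(
        profile,
        to_bed_mean=_time_from_hsn(tb),
        arise_mean=_time_from_hsn(ar),
        exit_rate=profile.exit_rate * float(np.exp(exit_log_scale * z)),
        exit_dur_mean=profile.exit_dur_mean * float(np.exp(0.1 * z)),
    )


# ---------------------------------------------------------------------------
# minute-level generation


#: beta concentration of night-to-night snore-propensity variation
SNORE_KAPPA = 15.0


def _night_snore_prob(profile: NightProfile, rng) -> float:
    p = profile.snore_prob
    if p <= 0 or p >= 1:
        return float(p)
    return float(rng.beta(p * SNORE_KAPPA, (1 - p) * SNORE_KAPPA))


def _sample_interval(profile: NightProfile, rng) -> tuple[int, int]:
    """Sampled (start, end) in-bed minute indices since noon, inclusive."""
    mu_tb = hours_since_noon(profile.to_bed_mean)
    mu_ar = hours_since_noon(profile.arise_mean)
    if mu_ar <= mu_tb:
        raise ValueError("degenerate profile: arise is not after to-bed within the night")
    for _ in range(64):
        tb = rng.normal(mu_tb, profile.to_bed_sd)
        ar = rng.normal(mu_ar, profile.arise_sd)
        if 0.0 <= tb and ar <= 23.99 and ar - tb >= 1.0:
            break
    else:  # extreme draws: fall back to clamped values
        tb = float(np.clip(rng.normal(mu_tb, profile.to_bed_sd), 0.0, 22.0))
        ar = float(np.clip(rng.normal(mu_ar, profile.arise_sd), tb + 1.0, 23.99))
    return int(round(tb * 60)), min(int(round(ar * 60)), 1439)


def _place_exits(start: int, end: int, profile: NightProfile, rng) -> set[int]:
    """Absent-minute indices for sampled bed exits (never touching the ends)."""
    n_exits = rng.poisson(profile.exit_rate)
    absent: set[int] = set()
    if n_exits == 0 or profile.exit_dur_mean <= 0 or end - start < 5:
        return absent
    sigma = 0.9
    mu = np.log(profile.exit_dur_mean) - sigma**2 / 2
    for _ in range(n_exits):
        dur = max(1, int(round(rng.lognormal(mu, sigma))))
        # an absence of >= 30 min is a separate bed episode downstream, not
        # an exit, so exit durations are truncated below that threshold
        dur = min(dur, 29, (end - start) // 2)
        lo, hi = start + 1, end - dur - 1
        if hi <= lo:
            continue
        onset = int(rng.integers(lo, hi + 1))
        span = range(onset, onset + dur)
        # keep >= 1 occupied minute between exits so each planted exit stays distinct
        guard = range(onset - 1, onset + dur + 1)
        if any(m in absent for m in guard):
            continue
        absent.update(span)
    return absent


def _markov_states(n: int, P: np.ndarray, rng) -> np.ndarray:
    states = np.empty(n, dtype=np.int64)
    cum = np.cumsum(P, axis=1)
    s = 1  # chain starts in LIGHT
    u = rng.random(n)
    for i in range(n):
        s = int(np.searchsorted(cum[s], u[i]))
        states[i] = s
    return states


def generate_night(profile: NightProfile, date: dt.date, rng,
                   return_truth: bool = False):
    """One night's minute observations inside the [noon, next-noon) window.

    Returns a DataFrame with the minute-observation schema (no participant
    column); with ``return_truth=True`` also returns a dict of the realized
    in-bed interval and exit structure for recovery tests.
    """
    rng = as_rng(rng)
    start, end = _sample_interval(profile, rng)
    absent = _place_exits(start, end, profile, rng)
    minutes = [m for m in range(start, end + 1) if m not in absent]

    nap_minutes: list[int] = []
    if profile.nap_prob > 0 and rng.random() < profile.nap_prob:
        nap_len = int(np.clip(round(rng.lognormal(np.log(45) - 0.32, 0.8)), 10, 120))
        nap_start = int(rng.integers(60, 300))  # 13:00-17:00
        if nap_start + nap_len < min(start, 480) - 45:
            nap_minutes = list(range(nap_start, nap_start + nap_len))

    all_minutes = nap_minutes + minutes
    noon = dt.datetime.combine(date, dt.time(12, 0))
    ts = [noon + dt.timedelta(minutes=m) for m in all_minutes]
    n = len(all_minutes)
    states = _markov_states(n, profile.state_transition, rng)
    obs = pd.DataFrame(
        {
            "timestamp": ts,
            "heart_rate": np.clip(rng.normal(profile.hr_mean, profile.hr_sd, n), 30, 200),
            "respiration_rate": np.clip(rng.normal(profile.rr_mean, profile.rr_sd, n), 4, 60),
            "snoring": (rng.random(n) < _night_snore_prob(profile, rng)).astype(int),
            "state": [STATES[s] for s in states],
        }
    )
    if not return_truth:
        return obs
    runs = _runs(sorted(absent))
    truth = {
        "start_minute": start,
        "end_minute": end,
        "n_exits": len(runs),
        "exit_minutes": [len(r) for r in runs],
        "nap_minutes": len(nap_minutes),
    }
    return obs, truth


def _runs(sorted_idx):
    out, cur = [], []
    for m in sorted_idx:
        if cur and m == cur[-1] + 1:
            cur.append(m)
        else:
            if cur:
                out.append(cur)
            cur = [m]
    if cur:
        out.append(cur)
    return out


# ---------------------------------------------------------------------------
# cohort-level generation


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_participants: int
    nights_per_participant: int
    profile: NightProfile
    disturbance_sd: float = 1.0

    def __post_init__(self):
        if self.n_participants < 1 or self.nights_per_participant < 1:
            raise ValueError("n_participants and nights_per_participant must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: list
    assessment_schedule: dict = field(
        default_factory=lambda: {"ADAS-Cog": 180, "PSQI": 180, "NPI": 90, "BADL": 90}
    )
    #: scale -> (intercept, slope on latent disturbance, noise sd)
    effect_map: dict = field(
        default_factory=lambda: {
            "ADAS-Cog": (20.0, 2.0, 4.0),
            "NPI": (12.0, 3.0, 5.0),
            "BADL": (15.0, 4.0, 3.0),
            "PSQI": (7.0, 0.5, 2.0),
        }
    )
    seed: int = 0
    start_date: dt.date = dt.date(2021, 1, 4)


def generate_cohort(spec: CohortSpec):
    """Generate (minute table, assessment table, latent truth table).

    One minute stream per participant-night; assessment scores are linear in
    the participant's latent disturbance plus Gaussian noise; the truth table
    retains all sampled per-night parameters for recovery tests.
    """
    labels = [
        f"{g.label}-{i:03d}" for g in spec.groups for i in range(g.n_participants)
    ]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate participant labels across groups")

    minute_frames, assess_rows, truth_rows = [], [], []
    for g in spec.groups:
        for i in range(g.n_participants):
            pid = f"{g.label}-{i:03d}"
            p_rng = child_rng(spec.seed, g.label, i)
            z = float(p_rng.normal(0, g.disturbance_sd))
            prof = perturb_profile(g.profile, z)
            for j in range(g.nights_per_participant):
                date = spec.start_date + dt.timedelta(days=j)
                obs, truth = generate_night(
                    prof, date, child_rng(spec.seed, g.label, i, "night", j),
                    return_truth=True,
                )
                obs.insert(0, "participant_id", pid)
                minute_frames.append(obs)
                truth_rows.append(
                    {"participant_id": pid, "group": g.label, "night_date": date,
                     "latent_disturbance": z, **{k: v for k, v in truth.items()
                                                 if k != "exit_minutes"},
                     "exit_minutes_total": sum(truth["exit_minutes"])}
                )
            span = g.nights_per_participant
            for scale, interval in spec.assessment_schedule.items():
                b0, b1, sd = spec.effect_map.get(scale, (0.0, 0.0, 1.0))
                k = 1
                while k * interval <= span:
                    a_date = spec.start_date + dt.timedelta(days=k * interval)
                    score = b0 + b1 * z + sd * p_rng.normal()
                    assess_rows.append(
                        {"participant_id": pid, "assessment_date": a_date,
                         "scale": scale, "score": float(score)}
                    )
                    k += 1
    minute_table = pd.concat(minute_frames, ignore_index=True)[MINUTE_COLUMNS]
    assessments = pd.DataFrame(
        assess_rows, columns=["participant_id", "assessment_date", "scale", "score"]
    )
    truth = pd.DataFrame(truth_rows)
    return minute_table, assessments, truth


# ---------------------------------------------------------------------------
# fast night-level sampler (no minute synthesis)


def sample_night_records(profile: NightProfile, n_nights: int, rng,
                         participant_id: str = "P-000",
                         start_date: dt.date = dt.date(2021, 1, 4),
                         state_concentration: float = 60.0) -> pd.DataFrame:
    """Draw nightly metric rows directly from the profile's distributions.

    Produces the same per-night metric table as the minute pipeline
    (timing angles, occupancy durations, exits, state mixture, physiology)
    without materializing minute observations — used for large cohort-scale
    model experiments where tens of thousands of nights are needed.
    """
    rng = as_rng(rng)
    mu_tb = hours_since_noon(profile.to_bed_mean)
    mu_ar = hours_since_noon(profile.arise_mean)
    tb = np.clip(rng.normal(mu_tb, profile.to_bed_sd, n_nights), 0.0, 22.0)
    ar = np.clip(rng.normal(mu_ar, profile.arise_sd, n_nights), tb + 1.0, 23.98)
    tb = np.round(tb * 60) / 60
    ar = np.round(ar * 60) / 60
    nop = ar - tb

    exits = rng.poisson(profile.exit_rate, n_nights)
    sigma = 0.9
    mu = np.log(max(profile.exit_dur_mean, 1e-9)) - sigma**2 / 2
    total = int(exits.sum())
    durs = rng.lognormal(mu, sigma, total) if total else np.empty(0)
    obt_min = np.zeros(n_nights)
    if total:
        idx = np.repeat(np.arange(n_nights), exits)
        np.add.at(obt_min, idx, np.clip(np.round(durs), 1.0, 29.0))
    obt_min = np.minimum(obt_min, nop * 60 * 0.45)
    obt_min = np.round(obt_min)
    obt_min[exits == 0] = 0.0
    ibt = nop - obt_min / 60
    exit_dur = np.where(exits > 0, obt_min / np.maximum(exits, 1), 0.0)

    props = rng.dirichlet(profile.stationary_states * state_concentration, n_nights)
    hr = np.clip(rng.normal(profile.hr_mean, profile.hr_sd / np.sqrt(30), n_nights), 30, 200)
    rr = np.clip(rng.normal(profile.rr_mean, profile.rr_sd / np.sqrt(30), n_nights), 4, 60)
    ibt_min = np.maximum(np.round(ibt * 60).astype(int), 1)
    if 0 < profile.snore_prob < 1:
        p_night = rng.beta(profile.snore_prob * SNORE_KAPPA,
                           (1 - profile.snore_prob) * SNORE_KAPPA, n_nights)
    else:
        p_night = np.full(n_nights, profile.snore_prob)
    snt = rng.binomial(ibt_min, p_night)

    dates = [start_date + dt.timedelta(days=int(j)) for j in range(n_nights)]
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "night_date": dates,
            "to_bed": [_time_from_hsn(h) for h in tb],
            "wake_up": [_time_from_hsn(h) for h in ar],
            "TO_BED": tb * 15.0,
            "ARISE": ((ar + 12) % 24) * 15.0,
            "NOP": nop,
            "IBT": ibt,
            "IBP": ibt / nop,
            "OBT": obt_min / 60,
            "EXITS": exits,
            "EXIT_DUR": exit_dur,
            "DEEP_DUR": props[:, 2] * ibt,
            "AWAKE_DUR": props[:, 0] * ibt,
            "REM_DUR": props[:, 3] * ibt,
            "LIGHT_DUR": props[:, 1] * ibt,
            "SNT": snt.astype(float),
            "WSA_DEEP": props[:, 2],
            "WSA_AWAKE": props[:, 0],
            "WSA_REM": props[:, 3],
            "WSA_LIGHT": props[:, 1],
            "HR": hr,
            "RR": rr,
            "SNR": snt / ibt_min,
        }
    )


def cohort_night_records(groups, seed: int, disturbance_sd: float = 0.4,
                         demographics: bool = True) -> pd.DataFrame:
    """Night-level metric table for a multi-group cohort.

    ``groups`` is a list of (label, n_participants, nights_per_participant,
    NightProfile). Participant heterogeneity is kept modest by default
    (``disturbance_sd=0.4``) so group-level contrasts dominate; set 0 for an
    exchangeable null. With ``demographics=True`` an age/sex column pair is
    attached (ages drawn around 82 for 'AD'-labelled groups, 81 otherwise).
    """
    frames = []
    for label, n_part, n_nights, profile in groups:
        for i in range(n_part):
            pid = f"{label}-{i:03d}"
            rng = child_rng(seed, "records", label, i)
            z = float(rng.normal(0, disturbance_sd))
            prof = perturb_profile(profile, z)
            df = sample_night_records(prof, n_nights, rng, participant_id=pid)
            df.insert(1, "group", label)
            df["latent_disturbance"] = z
            if demographics:
                base_age = 82.2 if label.upper().startswith("AD") else 81.3
                df["age"] = float(np.clip(rng.normal(base_age, 7.5), 60, 100))
                df["sex"] = int(rng.random() < 0.5)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
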