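"""90-day pre-assessment sleep-state profiles and group-effect statistics.

For each clinical assessment, the nights in the half-open 90-day window
before the assessment date are summarized as the proportion of nights in
each sleep-wake cluster (windows with < 15 distinct nights of data are
excluded). Window profiles are clustered with Ward linkage on pairwise
Hellinger distances (proportion vectors are already distributions, so no
binning is needed), with K chosen by Davies-Bouldin over 2..8; participants
are clustered the same way but with complete linkage and K by maximum
silhouette, mirroring the two linkage conventions of the two levels.

Group effects on outcomes use Welch's heteroscedasticity-robust ANOVA with
classical eta-squared, a Levene test for homoscedasticity, Games-Howell
post hoc pairwise comparisons (Hedges' g effect sizes, studentized-range
p-values), and Bonferroni correction across the outcome family at
alpha = 0.05. The Welch and Games-Howell statistics are computed from the
published closed forms:

    w_i = n_i / s_i^2,  F = [sum w_i (m_i - m_w)^2 / (K-1)] /
          [1 + 2(K-2)/(K^2-1) * sum (1 - w_i/W)^2 / (n_i - 1)]

with df1 = K - 1 and df2 = (K^2 - 1) / (3 sum (1 - w_i/W)^2 / (n_i - 1)).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f as f_dist
from scipy.stats import levene, studentized_range
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .cohort_stats import hellinger_probs

WINDOW_DAYS = 90
MIN_DAYS_WITH_DATA = 15
BEHAVIORAL_METRICS = ["IBT", "OBT", "EXITS", "EXIT_DUR"]


@dataclass(frozen=True)
class WindowProfile:
    participant_id: str
    assessment_date: dt.date
    n_nights_with_data: int
    state_proportions: np.ndarray
    behavioral_means: dict
    scores: dict  # scale -> score at this assessment


def build_windows(assessments: pd.DataFrame, night_labels: pd.DataFrame,
                  n_states: int | None = None,
                  window_days: int = WINDOW_DAYS,
                  min_days: int = MIN_DAYS_WITH_DATA) -> list[WindowProfile]:
    """One profile per retained assessment.

    ``night_labels`` needs participant_id, night_date and a ``state`` column
    of sleep-wake cluster labels (1..K); behavioral metric columns are
    averaged into the profile when present. ``assessments`` rows share an
    assessment when (participant, date) coincide; their scales fold into one
    profile's score dict.
    """
    labels = night_labels.copy()
    labels["night_date"] = pd.to_datetime(labels["night_date"]).dt.date
    if n_states is None:
        n_states = int(labels["state"].max())
    metrics_present = [m for m in BEHAVIORAL_METRICS if m in labels.columns]
    profiles = []
    by_pid = dict(tuple(labels.groupby("participant_id")))
    grouped = assessments.copy()
    grouped["assessment_date"] = pd.to_datetime(grouped["assessment_date"]).dt.date
    for (pid, date), sub in grouped.groupby(["participant_id", "assessment_date"]):
        nights = by_pid.get(pid)
        if nights is None:
            continue
        lo = date - dt.timedelta(days=window_days)
        in_win = nights[(nights["night_date"] >= lo) & (nights["night_date"] < date)]
        n_days = in_win["night_date"].nunique()
        if n_days < min_days:
            continue
        counts = np.bincount(in_win["state"].astype(int), minlength=n_states + 1)[1:]
        props = counts / counts.sum()
        profiles.append(
            WindowProfile(
                participant_id=str(pid), assessment_date=date,
                n_nights_with_data=int(n_days),
                state_proportions=props,
                behavioral_means={m: float(in_win[m].mean()) for m in metrics_present},
                scores=dict(zip(sub["scale"], sub["score"])),
            )
        )
    return profiles


def hellinger_condensed(proportions: np.ndarray) -> np.ndarray:
    """Condensed pairwise Hellinger distances between proportion rows."""
    sq = np.sqrt(np.asarray(proportions, dtype=float))
    diff = sq[:, None, :] - sq[None, :, :]
    full = np.sqrt(0.5 * np.sum(diff**2, axis=2))
    return squareform(full, checks=False)


def _select_k(Z, dist_condensed, features, k_range, criterion):
    scores = {}
    D = squareform(dist_condensed)
    for k in k_range:
        lab = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        if criterion == "davies_bouldin":
            scores[k] = float(davies_bouldin_score(features, lab))
        else:  # silhouette on the precomputed distance
            scores[k] = float(silhouette_score(D, lab, metric="precomputed"))
    if criterion == "davies_bouldin":
        best = min(scores, key=lambda k: (scores[k], k))
    else:
        best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def cluster_windows(profiles: list[WindowProfile], k_range=range(2, 9)):
    """Assessment-state labels: Ward on Hellinger distances, K by Davies-Bouldin."""
    if len(profiles) < 8:
        raise ValueError("need >= 8 window profiles to cluster")
    P = np.stack([p.state_proportions for p in profiles])
    d = hellinger_condensed(P)
    Z = linkage(d, method="ward")
    best, scores = _select_k(Z, d, P, list(k_range), "davies_bouldin")
    labels = fcluster(Z, best, criterion="maxclust")
    return labels, {"k": int(best), "scores": scores, "linkage": Z}


def cluster_participants(proportions: pd.DataFrame, k_range=range(2, 9)):
    """Dementia-group labels per participant.

    ``proportions`` is indexed by participant with one sleep-state proportion
    column per cluster. Complete linkage on Hellinger distances; K by maximum
    silhouette. Following the usual silhouette rule of thumb, a best score
    <= 0.5 is flagged as weak structure (noise-only inputs typically score
    ~0.3 at this sample size, well-separated archetypes > 0.7).
    """
    if len(proportions) < 4:
        raise ValueError("need >= 4 participants to cluster")
    P = proportions.to_numpy(float)
    d = hellinger_condensed(P)
    Z = linkage(d, method="complete")
    best, scores = _select_k(Z, d, P, list(k_range), "silhouette")
    labels = fcluster(Z, best, criterion="maxclust")
    info = {"k": int(best), "scores": scores, "linkage": Z,
            "weak_structure": scores[best] <= 0.5}
    return pd.Series(labels, index=proportions.index, name="dementia_group"), info


# ---------------------------------------------------------------------------
# Welch ANOVA / Games-Howell


VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class GroupEffectReport:
    outcome: str
    welch_f: float
    df1: float
    df2: float
    p: float
    eta_squared: float
    levene_stat: float
    levene_p: float
    pairwise: pd.DataFrame  # Games-Howell table
    bonferroni_p: float
    significant: bool
    zero_variance_groups: tuple = ()


def welch_anova_f(groups) -> tuple[float, float, float, float]:
    """(F, df1, df2, p) of Welch's ANOVA from the closed form."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    s2 = np.maximum(np.array([g.var(ddof=1) for g in groups]), VARIANCE_FLOOR)
    w = n / s2
    W = w.sum()
    mw = (w * m).sum() / W
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = 3 * ((1 - w / W) ** 2 / (n - 1)).sum() / (k**2 - 1)
    F = num / (1 + 2 * (k - 2) / 3 * lam)
    df1 = k - 1.0
    df2 = 1.0 / lam
    p = float(f_dist.sf(F, df1, df2))
    return float(F), df1, df2, p


def eta_squared(groups) -> float:
    """Classical eta-squared: between-group SS over total SS."""
    allv = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    sst = ((allv - grand) ** 2).sum()
    return float(ssb / sst) if sst > 0 else 0.0


def games_howell(groups, labels=None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (Welch t, studentized-range p).

    Returns K(K-1)/2 rows with mean difference, Hedges' g, and the adjusted
    p-value from the studentized range distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    labels = list(labels) if labels is not None else list(range(1, k + 1))
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    s2 = np.maximum(np.array([g.var(ddof=1) for g in groups]), VARIANCE_FLOOR)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = s2[i] / n[i] + s2[j] / n[j]
            t = (m[i] - m[j]) / np.sqrt(se2)
            df = se2**2 / (
                (s2[i] / n[i]) ** 2 / (n[i] - 1) + (s2[j] / n[j]) ** 2 / (n[j] - 1)
            )
            p = float(studentized_range.sf(abs(t) * np.sqrt(2), k, df))
            sp = np.sqrt(((n[i] - 1) * s2[i] + (n[j] - 1) * s2[j]) / (n[i] + n[j] - 2))
            g_unc = (m[i] - m[j]) / sp if sp > 0 else 0.0
            corr = 1 - 3 / (4 * (n[i] + n[j]) - 9)
            rows.append(
                {"group_a": labels[i], "group_b": labels[j],
                 "mean_diff": float(m[i] - m[j]), "hedges_g": float(g_unc * corr),
                 "t": float(t), "df": float(df), "p_adjusted": min(p, 1.0)}
            )
    return pd.DataFrame(rows)


def group_effects(df: pd.DataFrame, group_col: str, outcomes,
                  alpha: float = 0.05) -> list[GroupEffectReport]:
    """One report per outcome with Bonferroni correction across the family."""
    outcomes = list(outcomes)
    n_tests = len(outcomes)
    reports = []
    for outcome in outcomes:
        sub = df[[group_col, outcome]].dropna()
        grouped = [g[outcome].to_numpy(float) for _, g in sub.groupby(group_col)]
        names = [name for name, _ in sub.groupby(group_col)]
        if len(grouped) < 2 or any(len(g) < 3 for g in grouped):
            raise ValueError(f"outcome {outcome!r}: need >= 2 groups with >= 3 observations")
        zero_var = tuple(
            names[i] for i, g in enumerate(grouped) if np.var(g, ddof=1) <= VARIANCE_FLOOR
        )
        F, df1, df2, p = welch_anova_f(grouped)
        lv_stat, lv_p = levene(*grouped, center="median")
        p_bonf = min(p * n_tests, 1.0)
        reports.append(
            GroupEffectReport(
                outcome=outcome, welch_f=F, df1=df1, df2=df2, p=p,
                eta_squared=eta_squared(grouped),
                levene_stat=float(lv_stat), levene_p=float(lv_p),
                pairwise=games_howell(grouped, names),
                bonferroni_p=p_bonf, significant=p_bonf < alpha,
                zero_variance_groups=zero_var,
            )
        )
    return reports
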