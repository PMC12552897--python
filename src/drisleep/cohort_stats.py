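"""Distribution-level group comparison and cohort balancing.

Because cohort sizes can differ by orders of magnitude (tens of thousands of
sensor nights versus millions), classical two-sample tests are overpowered;
group contrasts are therefore expressed as Hellinger distances between binned
metric distributions,

    H(P, Q) = sqrt( 1/2 * sum_i (sqrt(p_i) - sqrt(q_i))^2 )  in [0, 1].

Sleep-timing association uses the Fisher-Lee circular correlation coefficient
with a percentile bootstrap CI, and case/control balancing uses logistic
propensity scores with greedy nearest-neighbour matching without replacement
(up to 10 controls per case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._rng import as_rng

#: canonical bin edges per metric: 50 equal-width bins over the
#: filter-admissible range (integer bins for exit counts).
CANONICAL_BINS = {
    "EXITS": np.arange(-0.5, 21.5, 1.0),
    "IBT": np.linspace(4, 16, 51),
    "IBP": np.linspace(0.6, 1.0, 51),
    "OBT": np.linspace(0, 3, 51),
    "NOP": np.linspace(4, 19, 51),
    "EXIT_DUR": np.linspace(0, 60, 51),
    "HR": np.linspace(45, 85, 51),
    "RR": np.linspace(10, 25, 51),
    "SNR": np.linspace(0, 1, 51),
    "TO_BED": np.linspace(0, 360, 51),
    "ARISE": np.linspace(0, 360, 51),
    "WSA_DEEP": np.linspace(0, 1, 51),
    "WSA_AWAKE": np.linspace(0, 1, 51),
    "WSA_REM": np.linspace(0, 1, 51),
    "WSA_LIGHT": np.linspace(0, 1, 51),
}


@dataclass(frozen=True)
class MetricDistribution:
    metric: str
    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        e = np.asarray(self.bin_edges, dtype=float)
        if len(p) != len(e) - 1:
            raise ValueError("need one probability per bin")
        if np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "bin_edges", e)


def bin_metric(values, bin_edges, metric: str = "") -> MetricDistribution:
    """Empirical binned distribution; out-of-range values clip to end bins."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("bin_metric needs at least one finite value")
    e = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(e) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    v = np.clip(v, e[0], e[-1])
    counts, _ = np.histogram(v, bins=e)
    return MetricDistribution(metric, e, counts / counts.sum())


def hellinger(P: MetricDistribution, Q: MetricDistribution) -> float:
    """Hellinger distance between two distributions on identical bins."""
    if not np.array_equal(P.bin_edges, Q.bin_edges):
        raise ValueError("distributions must share identical bin edges")
    return hellinger_probs(P.probabilities, Q.probabilities)


def hellinger_probs(p, q) -> float:
    """H(p, q) on raw probability vectors of equal length."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.sqrt(0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)))


def compare_groups(nights_by_group: dict, metrics,
                   bins: dict | None = None,
                   small_group_n: int = 30) -> pd.DataFrame:
    """Pairwise Hellinger distances per (group pair, metric), shared bins.

    Groups with fewer than ``small_group_n`` nights get a warning flag on
    their cells.
    """
    if len(nights_by_group) < 2:
        raise ValueError("need at least two groups to compare")
    bins = {**CANONICAL_BINS, **(bins or {})}
    labels = sorted(nights_by_group)
    rows = []
    for m in metrics:
        dists = {
            g: bin_metric(nights_by_group[g][m].to_numpy(), bins[m], m) for g in labels
        }
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                rows.append(
                    {
                        "metric": m, "group_a": a, "group_b": b,
                        "hellinger": hellinger(dists[a], dists[b]),
                        "small_sample": len(nights_by_group[a]) < small_group_n
                        or len(nights_by_group[b]) < small_group_n,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# circular statistics


def fisher_lee_correlation(theta, phi) -> float:
    """Fisher-Lee circular correlation between paired angle vectors (radians).

    O(n) computational form of the pairwise definition
    r = sum_{i<j} sin(t_i - t_j) sin(p_i - p_j) / sqrt(...).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n = len(theta)
    A = np.sum(np.cos(theta) * np.cos(phi))
    B = np.sum(np.sin(theta) * np.sin(phi))
    C = np.sum(np.cos(theta) * np.sin(phi))
    D = np.sum(np.sin(theta) * np.cos(phi))
    E = np.sum(np.cos(2 * theta))
    F = np.sum(np.sin(2 * theta))
    G = np.sum(np.cos(2 * phi))
    H = np.sum(np.sin(2 * phi))
    denom = np.sqrt((n**2 - E**2 - F**2) * (n**2 - G**2 - H**2))
    if denom == 0:
        return 0.0
    return float(4 * (A * B - C * D) / denom)


def circular_correlation(to_bed_angles, arise_angles, n_boot: int = 1000,
                         seed: int | np.random.Generator = 0,
                         degrees: bool = True):
    """(r, CI_low, CI_high): Fisher-Lee r with a percentile bootstrap CI."""
    theta = np.asarray(to_bed_angles, dtype=float)
    phi = np.asarray(arise_angles, dtype=float)
    if len(theta) != len(phi) or len(theta) < 10:
        raise ValueError("need >= 10 paired angles")
    if degrees:
        theta, phi = np.deg2rad(theta), np.deg2rad(phi)
    r = fisher_lee_correlation(theta, phi)
    rng = as_rng(seed)
    n = len(theta)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = fisher_lee_correlation(theta[idx], phi[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return r, float(lo), float(hi)


# ---------------------------------------------------------------------------
# propensity matching


@dataclass(frozen=True)
class MatchResult:
    matches: dict  # case id -> list of matched control ids (<= ratio)
    unmatched_cases: tuple
    coefficients: dict  # covariate -> logistic coefficient (plus intercept)
    balance: pd.DataFrame  # standardized mean differences pre/post match
    propensity: pd.Series  # id -> fitted propensity score


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1) if len(a) > 1 else 0.0
    vb = b.var(ddof=1) if len(b) > 1 else 0.0
    pooled = np.sqrt((va + vb) / 2)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def propensity_match(cases: pd.DataFrame, pool: pd.DataFrame,
                     covariates=("age", "sex"), ratio: int = 10,
                     id_col: str = "participant_id") -> MatchResult:
    """Greedy nearest-propensity matching without replacement.

    A logistic model of group membership on the covariates yields propensity
    scores; cases (processed in stable id order) each take up to ``ratio``
    nearest-score controls, ties broken by control id.
    """
    if pool.empty:
        raise ValueError("control pool is empty")
    if set(cases[id_col]) & set(pool[id_col]):
        raise ValueError("cases and pool must be disjoint")
    covariates = list(covariates)
    X = pd.concat([cases[covariates], pool[covariates]], ignore_index=True).to_numpy(float)
    y = np.r_[np.ones(len(cases)), np.zeros(len(pool))]
    model = LogisticRegression(C=np.inf, max_iter=1000).fit(X, y)
    ps = model.predict_proba(X)[:, 1]
    ids = pd.concat([cases[id_col], pool[id_col]], ignore_index=True)
    propensity = pd.Series(ps, index=ids.to_numpy())

    case_ids = sorted(cases[id_col].astype(str))
    pool_df = pd.DataFrame({"id": pool[id_col].astype(str).to_numpy(),
                            "ps": propensity.loc[pool[id_col]].to_numpy()})
    available = dict(zip(pool_df["id"], pool_df["ps"]))
    matches, unmatched = {}, []
    for cid in case_ids:
        cps = float(propensity.loc[cid])
        ranked = sorted(available.items(), key=lambda kv: (abs(kv[1] - cps), kv[0]))
        chosen = [cid2 for cid2, _ in ranked[:ratio]]
        for c in chosen:
            del available[c]
        if chosen:
            matches[cid] = chosen
        else:
            unmatched.append(cid)

    matched_controls = [c for ms in matches.values() for c in ms]
    pool_idx = pool.set_index(pool[id_col].astype(str))
    bal_rows = []
    for cov in covariates:
        pre = _smd(cases[cov].to_numpy(float), pool[cov].to_numpy(float))
        post = (
            _smd(cases[cov].to_numpy(float),
                 pool_idx.loc[matched_controls, cov].to_numpy(float))
            if matched_controls else np.nan
        )
        bal_rows.append({"covariate": cov, "smd_pre": pre, "smd_post": post})
    coefs = dict(zip(covariates, model.coef_[0]))
    coefs["intercept"] = float(model.intercept_[0])
    return MatchResult(matches, tuple(unmatched), coefs,
                       pd.DataFrame(bal_rows), propensity)
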