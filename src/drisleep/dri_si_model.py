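"""The DRI-SI-AD nightly sleep-disturbance index.

An ensemble of interpretable additive boosted binary classifiers (depth-1
gradient-boosted trees) scores each night's metric vector with the
probability that the night resembles the Alzheimer's-disease cohort. The
training protocol guards against participant and temporal leakage:

1.  **Multi-level split** — a stratified ~10% of participants is held out
    entirely (naive test, round-half-down per class); of the remainder, each
    participant's last 30 days form the horizon test; all other nights are
    the training universe.
2.  **Iterative fitting** — each ensemble member draws a stratified bootstrap
    of participants within class, subsamples each participant's timeline with
    quasi-random temporal sampling (the timeline is cut into 10 equal blocks
    and one night per block per pass is picked at a van der Corput
    low-discrepancy position, preserving temporal order and spread), then
    randomly under-samples the majority class to 1:1 before fitting. Nights
    of out-of-bootstrap participants give an internal test metric; a random
    15% night-level holdout of the training sample gives an internal
    validation metric.
3.  **Merge** — member case-class probabilities are averaged; the ensemble
    score is therefore bounded in [0, 1].

Evaluation reports sensitivity, specificity, per-class precision, F1, the
Matthews correlation coefficient and AUC-ROC, alongside a dummy baseline of
the same architecture trained on label-shuffled data. Feature importance is
the mean drop in held-out F1 under per-feature value shuffling. Nightly
scores map to six equal-width categories on [0, 1] (half-open bins, top bin
closed), category 6 being most AD-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import f1_score, matthews_corrcoef, precision_score, recall_score, roc_auc_score

from ._rng import as_rng, child_rng

DEFAULT_FEATURES = [
    "TO_BED", "ARISE", "NOP", "IBT", "IBP", "OBT", "EXITS", "EXIT_DUR",
    "WSA_DEEP", "WSA_AWAKE", "WSA_REM", "WSA_LIGHT", "HR", "RR", "SNR",
]

N_TEMPORAL_BLOCKS = 10


@dataclass(frozen=True)
class SplitPlan:
    naive_participants: tuple
    train_index: np.ndarray  # positional indices into the nights table
    horizon_index: np.ndarray
    naive_index: np.ndarray
    notes: tuple = ()


def _round_half_down(x: float) -> int:
    return int(np.ceil(x - 0.5))


def split_multilevel(nights: pd.DataFrame, label_col: str = "is_case",
                     naive_fraction: float = 0.1, horizon_days: int = 30,
                     seed: int = 0) -> SplitPlan:
    """Participant-stratified naive split plus per-participant horizon tail."""
    rng = as_rng(seed)
    dates = pd.to_datetime(nights["night_date"])
    naive_parts, notes = [], []
    for cls, sub in nights.groupby(label_col):
        parts = np.array(sorted(sub["participant_id"].unique()))
        if len(parts) < 10:
            raise ValueError("need >= 10 participants per class")
        m = _round_half_down(len(parts) * naive_fraction)
        naive_parts.extend(rng.choice(parts, size=m, replace=False))
    naive_set = set(naive_parts)
    is_naive = nights["participant_id"].isin(naive_set).to_numpy()

    horizon = np.zeros(len(nights), dtype=bool)
    for pid, sub in nights[~is_naive].groupby("participant_id"):
        d = dates.loc[sub.index]
        cutoff = d.max() - pd.Timedelta(days=horizon_days)
        tail = d > cutoff
        if tail.all():
            # participant's whole span fits in the horizon window: keep these
            # nights in training so the participant still contributes
            notes.append(f"{pid}: span <= {horizon_days} d, all nights kept in train")
            continue
        horizon[sub.index[tail]] = True
    train = ~(is_naive | horizon)
    return SplitPlan(
        naive_participants=tuple(sorted(naive_set)),
        train_index=np.flatnonzero(train),
        horizon_index=np.flatnonzero(horizon),
        naive_index=np.flatnonzero(is_naive),
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# iterative fitting


def van_der_corput(i: int, base: int = 2) -> float:
    """i-th element of the base-b van der Corput low-discrepancy sequence."""
    v, denom = 0.0, 1.0
    while i:
        i, rem = divmod(i, base)
        denom *= base
        v += rem / denom
    return v


def temporal_subsample(n_nights: int, n_passes: int) -> np.ndarray:
    """Quasi-random temporal subsample of a sorted timeline of ``n_nights``.

    The timeline is split into 10 equal blocks; each pass picks one night per
    block at the van der Corput position for that pass, so successive passes
    spread deterministically across each block while temporal order is kept.
    """
    if n_nights <= N_TEMPORAL_BLOCKS:
        return np.arange(n_nights)
    edges = np.linspace(0, n_nights, N_TEMPORAL_BLOCKS + 1).astype(int)
    picks = set()
    for p in range(1, n_passes + 1):
        u = van_der_corput(p)
        for b in range(N_TEMPORAL_BLOCKS):
            lo, hi = edges[b], edges[b + 1]
            if hi > lo:
                picks.add(lo + int(u * (hi - lo)))
    return np.array(sorted(picks))


def _shallow_binary(seed: int) -> GradientBoostingClassifier:
    # depth-1 trees => additive per-feature model ("extremely shallow trees")
    return GradientBoostingClassifier(
        n_estimators=150, max_depth=1, learning_rate=0.1, random_state=seed
    )


@dataclass
class MemberModel:
    model: GradientBoostingClassifier
    seed: int
    sampled_night_index: np.ndarray  # rows of the training universe used
    internal_test: dict = field(default_factory=dict)
    internal_validation: dict = field(default_factory=dict)


def fit_iteration(train_nights: pd.DataFrame, features, label_col: str,
                  iteration_seed: int, n_passes: int = 3) -> MemberModel:
    """One ensemble member: bootstrap, temporal subsample, under-sample, fit."""
    rng = as_rng(iteration_seed)
    classes = sorted(train_nights[label_col].unique())
    if len(classes) != 2:
        raise ValueError("training universe must contain both classes")
    parts_by_class = {
        c: np.array(sorted(train_nights.loc[train_nights[label_col] == c,
                                            "participant_id"].unique()))
        for c in classes
    }
    for _ in range(10):
        boot = {c: rng.choice(p, size=len(p), replace=True)
                for c, p in parts_by_class.items()}
        if all(len(b) for b in boot.values()):
            break

    by_pid = train_nights.sort_values("night_date").groupby("participant_id")
    pid_rows = {pid: sub.index.to_numpy() for pid, sub in by_pid}
    sampled_rows: list[np.ndarray] = []
    for c in classes:
        for pid in boot[c]:
            rows = pid_rows[pid]
            sampled_rows.append(rows[temporal_subsample(len(rows), n_passes)])
    idx = np.concatenate(sampled_rows)
    sample = train_nights.loc[idx]

    # random under-sampling of the majority class to a 1:1 ratio
    counts = sample[label_col].value_counts()
    n_min = int(counts.min())
    kept_parts = []
    for c in classes:
        rows = np.flatnonzero((sample[label_col] == c).to_numpy())
        if len(rows) > n_min:
            rows = rng.choice(rows, size=n_min, replace=False)
        kept_parts.append(rows)
    kept = np.concatenate(kept_parts)
    balanced = sample.iloc[kept]

    # internal night-level validation holdout (15%)
    n = len(balanced)
    val_rows = rng.choice(n, size=max(1, int(0.15 * n)), replace=False)
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_rows] = True
    fit_df, val_df = balanced.iloc[~val_mask], balanced.iloc[val_mask]

    model = _shallow_binary(int(as_rng(iteration_seed).integers(2**31)))
    model.fit(fit_df[features].to_numpy(float), fit_df[label_col].to_numpy(int))

    oob = train_nights.loc[~train_nights["participant_id"].isin(
        np.concatenate([boot[c] for c in classes]))]
    member = MemberModel(model=model, seed=iteration_seed,
                         sampled_night_index=np.unique(idx))
    for name, part in (("internal_test", oob), ("internal_validation", val_df)):
        if len(part) and part[label_col].nunique() == 2:
            proba = model.predict_proba(part[features].to_numpy(float))[:, 1]
            y = part[label_col].to_numpy(int)
            setattr(member, name, {
                "auc": float(roc_auc_score(y, proba)),
                "f1": float(f1_score(y, proba >= 0.5)),
            })
    return member


@dataclass
class DriSiEnsemble:
    members: list
    features: list
    merge_rule: str = "average"

    def score(self, nights: pd.DataFrame) -> np.ndarray:
        """Ensemble nightly score: mean member case-class probability."""
        X = nights[self.features].to_numpy(float)
        probs = np.stack([m.model.predict_proba(X)[:, 1] for m in self.members])
        return probs.mean(axis=0)


def merge_ensemble(members: list, features=None) -> DriSiEnsemble:
    if not members:
        raise ValueError("need at least one member model")
    n_feat = members[0].model.n_features_in_
    if any(m.model.n_features_in_ != n_feat for m in members):
        raise ValueError("members disagree on feature count")
    return DriSiEnsemble(members=list(members), features=list(features or []))


def train_dri_si(nights: pd.DataFrame, label_col: str = "is_case",
                 features=DEFAULT_FEATURES, n_members: int = 50,
                 naive_fraction: float = 0.1, horizon_days: int = 30,
                 seed: int = 0):
    """Full protocol: split, iterate, merge. Returns (ensemble, plan)."""
    nights = nights.reset_index(drop=True)
    plan = split_multilevel(nights, label_col, naive_fraction, horizon_days,
                            seed=child_rng(seed, "split"))
    train = nights.loc[plan.train_index]
    members = []
    for it in range(n_members):
        member_seed = int(child_rng(seed, "member", it).integers(2**31))
        members.append(fit_iteration(train, list(features), label_col, member_seed))
    ensemble = merge_ensemble(members)
    ensemble.features = list(features)
    return ensemble, plan


def audit_leakage(plan: SplitPlan, ensemble: DriSiEnsemble) -> bool:
    """True iff no member's training sample touches naive or horizon nights."""
    held_out = set(plan.naive_index) | set(plan.horizon_index)
    return all(not (set(m.sampled_night_index) & held_out) for m in ensemble.members)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class EvalReport:
    dataset: str
    metrics: dict
    dummy_metrics: dict | None = None


def _binary_metrics(y, proba, threshold: float = 0.5) -> dict:
    pred = (np.asarray(proba) >= threshold).astype(int)
    y = np.asarray(y, dtype=int)
    out = {
        "sensitivity": recall_score(y, pred, pos_label=1, zero_division=0),
        "specificity": recall_score(y, pred, pos_label=0, zero_division=0),
        "precision_pos": precision_score(y, pred, pos_label=1, zero_division=0),
        "precision_neg": precision_score(y, pred, pos_label=0, zero_division=0),
        "f1": f1_score(y, pred, zero_division=0),
        "mcc": matthews_corrcoef(y, pred),
    }
    out["auc"] = float(roc_auc_score(y, proba)) if len(np.unique(y)) == 2 else np.nan
    return {k: float(v) for k, v in out.items()}


def evaluate(ensemble: DriSiEnsemble, nights: pd.DataFrame,
             label_col: str = "is_case", with_dummy: bool = True,
             seed: int = 0, dataset: str = "") -> EvalReport:
    """Threshold-0.5 metrics plus AUC; optional shuffled-label dummy baseline.

    The dummy shares the architecture of an ensemble member but is trained on
    label-shuffled data; its predictions are taken out-of-fold (2-fold) so the
    baseline reflects genuine absence of signal rather than memorization.
    """
    y = nights[label_col].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation needs both classes present (AUC undefined otherwise)")
    proba = ensemble.score(nights)
    metrics = _binary_metrics(y, proba)
    dummy = None
    if with_dummy:
        rng = as_rng(seed)
        y_shuf = rng.permutation(y)
        X = nights[ensemble.features].to_numpy(float)
        n = len(y)
        perm = rng.permutation(n)
        dummy_proba = np.empty(n)
        halves = (perm[: n // 2], perm[n // 2:])
        for fit_idx, pred_idx in (halves, halves[::-1]):
            dm = _shallow_binary(int(rng.integers(2**31)))
            dm.fit(X[fit_idx], y_shuf[fit_idx])
            dummy_proba[pred_idx] = dm.predict_proba(X[pred_idx])[:, 1]
        dummy = _binary_metrics(y, dummy_proba)
    return EvalReport(dataset=dataset, metrics=metrics, dummy_metrics=dummy)


def permutation_importance(ensemble: DriSiEnsemble, nights: pd.DataFrame,
                           label_col: str = "is_case", n_repeats: int = 5,
                           seed: int = 0) -> pd.DataFrame:
    """Mean and SD of (baseline F1 - shuffled F1) per feature on held-out data."""
    rng = as_rng(seed)
    y = nights[label_col].to_numpy(int)
    X = nights[ensemble.features].reset_index(drop=True)
    base = _binary_metrics(y, ensemble.score(X))["f1"]
    rows = []
    for feat in ensemble.features:
        drops = []
        for _ in range(n_repeats):
            Xs = X.copy()
            Xs[feat] = rng.permutation(Xs[feat].to_numpy())
            drops.append(base - _binary_metrics(y, ensemble.score(Xs))["f1"])
        rows.append({"feature": feat, "mean_f1_drop": float(np.mean(drops)),
                     "sd_f1_drop": float(np.std(drops, ddof=1)) if n_repeats > 1 else 0.0})
    return (pd.DataFrame(rows)
            .sort_values("mean_f1_drop", ascending=False)
            .reset_index(drop=True))


def categorize_scores(scores) -> np.ndarray:
    """Nightly scores -> categories 1..6 (equal-width half-open bins on [0,1],
    top bin closed; 6 is most AD-like)."""
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return np.minimum(np.floor(s * 6).astype(int) + 1, 6)
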