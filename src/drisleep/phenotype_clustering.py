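"""Night-level bed-occupancy phenotypes and the multi-class state classifier.

Step 1 (discovery): each standard night grid is reduced to 96 fifteen-minute
occupancy counts (noon to noon). Night-to-night dissimilarity combines, with
equal weight after dataset-wide min-max normalization,

* the Jaccard distance between the binary *non*-occupancy masks,
  J(X, Y) = 1 - |X n Y| / |X u Y| (0 when both masks are empty), and
* the Euclidean distance between the count vectors.

Hierarchical agglomerative clustering with Ward linkage is run on the
combined distance; the number of clusters is chosen by the minimum
Davies-Bouldin score over K = 2..10, and cluster labels are renumbered
1..K by descending mean occupied minutes so label 1 is always the
longest-occupancy phenotype.

Step 2 (external characterization): an interpretable additive boosted
classifier (depth-1 gradient-boosted trees, i.e. an additive model of
per-feature stumps) learns the cluster labels from the nightly timing
metrics (IBT, TO_BED, ARISE, NOP, OBT, EXITS, EXIT_DUR), evaluated with
leave-one-group-out cross-validation where each participant is a group, so
every night of a held-out participant is predicted by a model that never saw
that person.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import davies_bouldin_score, precision_score, recall_score, f1_score, accuracy_score
from sklearn.model_selection import LeaveOneGroupOut

from .ingest import MINUTES_PER_DAY, OccupancyGrid

N_BINS = 96
STATE_FEATURES = ["IBT", "TO_BED", "ARISE", "NOP", "OBT", "EXITS", "EXIT_DUR"]


@dataclass(frozen=True)
class NightAggregate:
    night: tuple  # (participant_id, night_date)
    bins: np.ndarray  # 96 counts of occupied minutes per 15-min bin
    mask: np.ndarray  # 96 binary non-occupancy indicators (1 iff bin empty)


def aggregate_15min(grid: OccupancyGrid) -> NightAggregate:
    """96-bin quarter-hour occupancy counts for a standard 1440-cell grid."""
    occ = np.asarray(grid.occupied, dtype=np.int64)
    if len(occ) != MINUTES_PER_DAY:
        raise ValueError("nonstandard grid length; night excluded from aggregation")
    bins = occ.reshape(N_BINS, 15).sum(axis=1)
    return NightAggregate(
        (grid.participant_id, grid.night_date), bins, (bins == 0).astype(np.uint8)
    )


def jaccard_mask_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - |X n Y| / |X u Y| on non-occupancy masks; 0 when both are empty."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    union = np.logical_or(x, y).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(x, y).sum() / union


@dataclass(frozen=True)
class DistanceNormalization:
    """Dataset-scoped min-max constants, persisted so new nights project
    consistently into the combined-distance space."""

    jaccard_min: float
    jaccard_max: float
    euclid_min: float
    euclid_max: float


def combined_distance_matrix(aggregates: list[NightAggregate],
                             norm: DistanceNormalization | None = None):
    """(condensed combined distance, normalization constants).

    Combined distance = mean of min-max-normalized Jaccard and Euclidean
    components, bounded in [0, 1].
    """
    masks = np.stack([a.mask for a in aggregates]).astype(np.float64)
    bins = np.stack([a.bins for a in aggregates]).astype(float)
    inter = masks @ masks.T
    sizes = masks.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac_full = np.where(union > 0, 1.0 - inter / union, 0.0)
    jac = squareform(jac_full, checks=False)
    euc = pdist(bins, metric="euclidean")
    if norm is None:
        norm = DistanceNormalization(
            float(jac.min()), float(jac.max()), float(euc.min()), float(euc.max())
        )

    def _norm(v, lo, hi):
        if hi - lo <= 0:
            return np.zeros_like(v)
        return np.clip((v - lo) / (hi - lo), 0.0, 1.0)

    combined = 0.5 * (_norm(jac, norm.jaccard_min, norm.jaccard_max)
                      + _norm(euc, norm.euclid_min, norm.euclid_max))
    return combined, norm


@dataclass
class SleepWakeClustering:
    labels: np.ndarray  # 1..K, renumbered by descending mean occupancy
    n_clusters: int
    linkage_tree: np.ndarray
    selection_scores: dict  # candidate K -> Davies-Bouldin score
    mean_occupancy: dict  # label -> mean occupied minutes
    normalization: DistanceNormalization
    nights: list = field(default_factory=list)


def cluster_nights(aggregates: list[NightAggregate],
                   k_range=range(2, 11)) -> SleepWakeClustering:
    """Ward clustering of nights on the combined distance, K by Davies-Bouldin.

    Deterministic given input order; rejects degenerate inputs where all
    pairwise distances vanish.
    """
    k_range = list(k_range)
    if len(aggregates) < max(k_range):
        raise ValueError("fewer nights than the largest candidate K")
    combined, norm = combined_distance_matrix(aggregates)
    if np.all(combined == 0):
        raise ValueError("degenerate input: all nights identical (zero-variance distances)")
    Z = linkage(combined, method="ward")
    feats = np.stack([a.bins for a in aggregates]).astype(float)
    scores = {}
    for k in k_range:
        lab = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        scores[k] = float(davies_bouldin_score(feats, lab))
    best_k = min(scores, key=lambda k: (scores[k], k))
    labels = fcluster(Z, best_k, criterion="maxclust")
    clustering = SleepWakeClustering(
        labels=labels, n_clusters=int(len(np.unique(labels))), linkage_tree=Z,
        selection_scores=scores, mean_occupancy={}, normalization=norm,
        nights=[a.night for a in aggregates],
    )
    return relabel_by_duration(clustering, aggregates)


def relabel_by_duration(clustering: SleepWakeClustering,
                        aggregates: list[NightAggregate]) -> SleepWakeClustering:
    """Renumber labels 1..K by descending mean occupied minutes.

    Ties break by larger cluster size, then by original label; idempotent.
    """
    occ = np.array([a.bins.sum() for a in aggregates], dtype=float)
    old = np.unique(clustering.labels)
    stats = []
    for lab in old:
        m = clustering.labels == lab
        stats.append((-occ[m].mean(), -m.sum(), lab))
    order = [lab for *_, lab in sorted(stats)]
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    new_labels = np.array([mapping[l] for l in clustering.labels])
    clustering.labels = new_labels
    clustering.mean_occupancy = {
        mapping[lab]: float(occ[clustering.labels == mapping[lab]].mean()) for lab in old
    }
    return clustering


# ---------------------------------------------------------------------------
# state classifier


def _shallow_multiclass(seed: int = 0) -> GradientBoostingClassifier:
    # depth-1 trees: one feature per term => strictly additive model
    return GradientBoostingClassifier(
        n_estimators=150, max_depth=1, learning_rate=0.1, random_state=seed
    )


@dataclass
class StateClassifier:
    features: list
    model: GradientBoostingClassifier
    cv_metrics: pd.DataFrame  # one row per held-out participant
    classes: np.ndarray

    def predict(self, nights: pd.DataFrame) -> np.ndarray:
        return assign_states(self, nights)


def _fold_metrics(y_true, y_pred) -> dict:
    return {
        "precision": precision_score(y_true, y_pred, average="macro", zero_division=0),
        "f1": f1_score(y_true, y_pred, average="macro", zero_division=0),
        "sensitivity": recall_score(y_true, y_pred, average="macro", zero_division=0),
        "accuracy": accuracy_score(y_true, y_pred),
    }


def train_state_classifier(nights: pd.DataFrame, labels, groups,
                           features=STATE_FEATURES, seed: int = 0) -> StateClassifier:
    """Leave-one-group-out CV (groups = participants) then refit on all data."""
    X = nights[features].to_numpy(float)
    y = np.asarray(labels)
    g = np.asarray(groups)
    if len(np.unique(g)) < 3:
        raise ValueError("need >= 3 participants for leave-one-group-out CV")
    rows = []
    logo = LeaveOneGroupOut()
    for tr, te in logo.split(X, y, g):
        if len(np.unique(y[tr])) < 2:
            rows.append({"participant": g[te][0], "skipped": True})
            continue
        m = _shallow_multiclass(seed).fit(X[tr], y[tr])
        pred = m.predict(X[te])
        rows.append({"participant": g[te][0], "skipped": False,
                     **_fold_metrics(y[te], pred)})
    cv = pd.DataFrame(rows)
    final = _shallow_multiclass(seed).fit(X, y)
    return StateClassifier(list(features), final, cv, final.classes_)


def assign_states(classifier: StateClassifier, nights: pd.DataFrame) -> np.ndarray:
    """Predicted sleep-wake cluster label per night (complete features only)."""
    X = nights[classifier.features]
    if X.isna().any().any():
        raise ValueError("nights with missing features cannot be labelled; drop them first")
    return classifier.model.predict(X.to_numpy(float))


def prevalence_chi2(labels_a, labels_b):
    """Chi-square test on the cluster prevalence table of two cohorts.

    Returns (chi2, p, standardized residual table); residuals with
    |r| > 2.58 flag cells over/under-represented at p < 0.01.
    """
    a = pd.Series(labels_a).value_counts()
    b = pd.Series(labels_b).value_counts()
    table = pd.DataFrame({"a": a, "b": b}).fillna(0).astype(int)
    chi2, p, _, expected = chi2_contingency(table.to_numpy())
    resid = (table.to_numpy() - expected) / np.sqrt(expected)
    return float(chi2), float(p), pd.DataFrame(resid, index=table.index, columns=table.columns)
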