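"""Metrics, stratified evaluation, clustering and distance analyses.

The recogniser's composition labels are zero-inflated: a modality is
absent from many aggregates, and a trivial always-absent predictor scores
high raw accuracy.  Evaluation therefore stratifies the test rows per
modality into a zero-labelled group (modality truly absent) and a
non-zero-labelled group (modality present and thus to be recognised), and
reports the within-group metrics alongside per-modality MCC / balanced
accuracy / F1 computed over rows whose label vector is not all-zero.

Because label columns and within-group truths are routinely single-class,
one degenerate-metric policy applies everywhere: an undefined MCC is
reported as 0.0 together with a ``degenerate`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)
from sklearn.mixture import GaussianMixture

__all__ = [
    "classification_metrics",
    "stratified_metrics",
    "StratifiedReport",
    "gmm_cluster",
    "GmmResult",
    "pca_project",
    "distance_analysis",
    "DistanceReport",
]


def _is_degenerate(y_true, y_pred) -> bool:
    return len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2


def classification_metrics(y_true, y_pred, labels=None) -> dict:
    """MCC, balanced accuracy, F1, precision, recall (+ confusion matrix).

    Multiclass inputs use macro averaging.  Single-class edge cases give
    MCC = 0.0 with ``degenerate`` set.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    avg = "binary" if labels is None and len(np.unique(y_true)) <= 2 else "macro"
    kw = {"average": avg, "zero_division": 0}
    if labels is not None:
        kw["labels"] = list(labels)
    degenerate = _is_degenerate(y_true, y_pred)
    return {
        "mcc": 0.0 if degenerate else float(matthews_corrcoef(y_true, y_pred)),
        "balanced_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
        "accuracy": float((y_true == y_pred).mean()),
        "f1": float(f1_score(y_true, y_pred, **kw)),
        "precision": float(precision_score(y_true, y_pred, **kw)),
        "recall": float(recall_score(y_true, y_pred, **kw)),
        "confusion_matrix": confusion_matrix(
            y_true, y_pred, labels=None if labels is None else list(labels)
        ),
        "degenerate": degenerate,
    }


@dataclass
class StratifiedReport:
    """Per-modality stratified metrics; one row per (modality, scope)."""

    table: pd.DataFrame

    def per_modality(self, modality: str) -> pd.DataFrame:
        return self.table[self.table["modality"] == modality]

    def nonzero_mcc(self) -> dict[str, float]:
        """Per-modality MCC over rows with at least one true modality."""
        sub = self.table[self.table["scope"] == "nonzero_rows"]
        return dict(zip(sub["modality"], sub["mcc"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stratified_metrics(
    Y_true: np.ndarray, Y_pred: np.ndarray, modalities
) -> StratifiedReport:
    """Stratified evaluation of multi-label composition predictions.

    For each modality three scopes are reported:

    * ``zero_group`` — rows where the modality is truly absent (the metric
      of interest is how often absence is correctly predicted);
    * ``nonzero_group`` — rows where the modality is truly present
      (recall-centric; exposes the trivial always-absent predictor);
    * ``nonzero_rows`` — rows whose whole label vector is not all-zero,
      with both classes of the modality present, on which MCC / balanced
      accuracy / F1 are well defined.
    """
    Y_true = np.asarray(Y_true)
    Y_pred = np.asarray(Y_pred)
    if Y_true.shape != Y_pred.shape:
        raise ValueError("shape mismatch between truths and predictions")
    if Y_true.shape[1] != len(modalities):
        raise ValueError("modality schema does not match label columns")
    any_true = Y_true.any(axis=1)
    rows = []
    for j, m in enumerate(modalities):
        yt, yp = Y_true[:, j], Y_pred[:, j]
        for scope, mask in (
            ("zero_group", yt == 0),
            ("nonzero_group", yt == 1),
            ("nonzero_rows", any_true),
        ):
            if mask.sum() == 0:
                rows.append(
                    {"modality": m, "scope": scope, "n": 0, "degenerate": True,
                     "mcc": 0.0, "balanced_accuracy": np.nan, "accuracy": np.nan,
                     "f1": np.nan, "precision": np.nan, "recall": np.nan}
                )
                continue
            met = classification_metrics(yt[mask], yp[mask])
            met.pop("confusion_matrix")
            rows.append({"modality": m, "scope": scope, "n": int(mask.sum()), **met})
    return StratifiedReport(pd.DataFrame(rows))


@dataclass
class GmmResult:
    assignments: np.ndarray  # raw component per sample
    mapping: dict[int, object]  # component -> cancer label
    aligned_labels: np.ndarray
    aligned_accuracy: float


def gmm_cluster(
    vectors: np.ndarray,
    labels: np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
    n_pca: int | None = 50,
) -> GmmResult:
    """Full-covariance GMM with one component per cancer type.

    Components are matched to cancer labels by the one-to-one assignment
    maximising agreement (Hungarian algorithm), and the resulting aligned
    accuracy is label-permutation invariant.  High-dimensional inputs are
    PCA-reduced first (default 50 components) so the full covariance stays
    well conditioned at cohort-scale sample sizes.
    """
    X = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    k = n_components if n_components is not None else len(classes)
    if X.shape[0] < k:
        raise ValueError("need at least n_components samples")
    if n_pca is not None and X.shape[1] > n_pca:
        X = PCA(n_components=min(n_pca, X.shape[0]), random_state=seed).fit_transform(X)
    gm = GaussianMixture(
        n_components=k, covariance_type="full", random_state=seed, reg_covar=1e-4
    )
    comp = gm.fit_predict(X)
    # contingency: component x class agreement counts
    cont = np.zeros((k, len(classes)), dtype=int)
    for c in range(k):
        for j, cl in enumerate(classes):
            cont[c, j] = int(((comp == c) & (labels == cl)).sum())
    ri, ci = linear_sum_assignment(-cont)
    mapping = {int(r): classes[c] for r, c in zip(ri, ci)}
    aligned = np.array([mapping.get(int(c), classes[0]) for c in comp])
    return GmmResult(
        assignments=comp,
        mapping=mapping,
        aligned_labels=aligned,
        aligned_accuracy=float((aligned == labels).mean()),
    )


def pca_project(vectors: np.ndarray, k: int = 2) -> np.ndarray:
    """Top-k principal-component scores with a fixed sign convention
    (largest-magnitude loading of each component is positive)."""
    X = np.asarray(vectors, dtype=np.float64)
    if X.shape[0] < k:
        raise ValueError("need at least k samples")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores


@dataclass
class DistanceReport:
    metric: str
    table: pd.DataFrame  # cancer_type, group(intra|inter), n_pairs, mean, q25, median, q75

    def intra_vs_inter(self) -> pd.DataFrame:
        return self.table.pivot(index="cancer_type", columns="group", values="mean")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def distance_analysis(
    vectors: np.ndarray, cancer_types: np.ndarray, metric: str = "euclidean"
) -> DistanceReport:
    """Intra- vs inter-type pairwise comparison summaries.

    ``euclidean`` is a distance (smaller = closer); ``cosine`` and ``dot``
    are reported as similarities (larger = closer).  Self-pairs are
    excluded; intra summaries use same-type pairs only.
    """
    X = np.asarray(vectors, dtype=np.float64)
    types = np.asarray(cancer_types)
    uniq = np.unique(types)
    if len(uniq) < 2:
        raise ValueError("need at least two cancer types for inter-type pairs")
    if metric == "euclidean":
        M = cdist(X, X, metric="euclidean")
    elif metric == "cosine":
        M = 1.0 - cdist(X, X, metric="cosine")  # similarity
    elif metric == "dot":
        M = X @ X.T
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = X.shape[0]
    off = ~np.eye(n, dtype=bool)
    rows = []
    for ct in uniq:
        in_ct = types == ct
        intra = M[np.ix_(in_ct, in_ct)][off[np.ix_(in_ct, in_ct)]]
        inter = M[np.ix_(in_ct, ~in_ct)].ravel()
        for group, vals in (("intra", intra), ("inter", inter)):
            if vals.size == 0:
                rows.append({"cancer_type": ct, "group": group, "n_pairs": 0,
                             "mean": np.nan, "q25": np.nan, "median": np.nan,
                             "q75": np.nan})
                continue
            rows.append(
                {
                    "cancer_type": ct,
                    "group": group,
                    "n_pairs": int(vals.size),
                    "mean": float(vals.mean()),
                    "q25": float(np.quantile(vals, 0.25)),
                    "median": float(np.quantile(vals, 0.5)),
                    "q75": float(np.quantile(vals, 0.75)),
                }
            )
    return DistanceReport(metric=metric, table=pd.DataFrame(rows))
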