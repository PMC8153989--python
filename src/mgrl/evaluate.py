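"""Negative sampling, pair-feature fusion, metrics and cross-validation.

The link-prediction task is binary: known drug-disease associations are
positives, and an equal-size uniform sample of unobserved pairs serves
as negatives (the standard balanced protocol for this task; the ratio
is configurable).  Each pair is represented by concatenating the two
endpoint rows of the graph-convolution features H and, in fused mode,
the two endpoint rows of the walk embedding E:

    [H_drug | H_disease | E_drug | E_disease]

Classification is by Random Forest (500 trees, sqrt features) under
stratified five-fold cross-validation; accuracy, sensitivity,
specificity, precision and MCC are computed from the 0.5-thresholded
confusion counts, AUC from the ROC rank statistic and AUPR from
precision-recall integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .io import AssociationTable

__all__ = [
    "LabeledPairSet",
    "sample_negatives",
    "fuse_features",
    "compute_metrics",
    "cross_validate",
    "rank_candidates",
    "make_classifier",
    "MGRLClassifier",
    "FEATURE_MODES",
    "CLASSIFIERS",
]

FEATURE_MODES = ("attribute", "embedding", "fused")
METRIC_NAMES = ("acc", "sen", "spec", "prec", "mcc", "auc", "aupr")


@dataclass(frozen=True)
class LabeledPairSet:
    """Positive pairs plus sampled negatives, with labels and the seed used."""

    pairs: tuple[tuple[str, str], ...]
    labels: np.ndarray
    seed: int


def sample_negatives(
    table: AssociationTable, ratio: float = 1.0, seed: int = 0
) -> LabeledPairSet:
    """Uniform negatives from the complement of the positive pair set.

    Samples ``ratio * n_positives`` (drug, disease) pairs never observed
    in the table, without replacement, deterministically for a seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    n_d, n_z = table.n_drugs, table.n_diseases
    positives = list(table.pairs)
    d_idx = {d: i for i, d in enumerate(table.drug_ids)}
    z_idx = {z: j for j, z in enumerate(table.disease_ids)}
    pos_index = {d_idx[d] * n_z + z_idx[z] for d, z in positives}
    n_neg = round(ratio * len(positives))
    complement_size = n_d * n_z - len(pos_index)
    if n_neg > complement_size:
        raise ValueError(
            f"requested {n_neg} negatives but only {complement_size} unobserved pairs exist"
        )
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n_d * n_z)
    mask = np.ones(n_d * n_z, dtype=bool)
    mask[list(pos_index)] = False
    chosen = rng.choice(all_idx[mask], size=n_neg, replace=False)
    negatives = [
        (table.drug_ids[i // n_z], table.disease_ids[i % n_z]) for i in sorted(chosen)
    ]
    pairs = tuple(positives + negatives)
    labels = np.concatenate([np.ones(len(positives)), np.zeros(n_neg)])
    return LabeledPairSet(pairs, labels, seed)


def fuse_features(
    pairs: Sequence[tuple[str, str]],
    node_index: Mapping[str, int],
    H: np.ndarray,
    E: np.ndarray,
    mode: str = "fused",
) -> np.ndarray:
    """Per-pair feature rows by endpoint-row concatenation.

    ``mode`` selects the ablation arm: ``attribute`` uses only the
    graph-convolution features H, ``embedding`` only the walk vectors E,
    ``fused`` concatenates both.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}; options: {FEATURE_MODES}")
    H = np.asarray(H, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    rows = []
    for drug, disease in pairs:
        if drug not in node_index or disease not in node_index:
            raise KeyError(f"pair ({drug!r}, {disease!r}) has a node outside the graph")
        i, j = node_index[drug], node_index[disease]
        blocks = []
        if mode in ("attribute", "fused"):
            blocks += [H[i], H[j]]
        if mode in ("embedding", "fused"):
            blocks += [E[i], E[j]]
        rows.append(np.concatenate(blocks))
    return np.vstack(rows)


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Single-fold classification metrics.

    Thresholded confusion counts give Acc, Sen, Spec, Prec and MCC;
    AUC is the midrank ROC statistic and AUPR the area under the
    precision-recall curve.  Requires both classes present.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same shape")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; metrics undefined")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0
    return {
        "acc": float(acc),
        "sen": float(sen),
        "spec": float(spec),
        "prec": float(prec),
        "mcc": float(mcc),
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
    }


CLASSIFIERS = ("rf", "svm", "logistic", "knn", "gbdt")


def make_classifier(name: str = "rf", seed: int = 0, **params):
    """Instantiate one of the supported classifiers with seeded defaults."""
    if name == "rf":
        defaults = dict(n_estimators=500, max_features="sqrt", n_jobs=1)
        defaults.update(params)
        return RandomForestClassifier(random_state=seed, **defaults)
    if name == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if name == "logistic":
        params.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}; options: {CLASSIFIERS}")


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    classifier: str = "rf",
    seed: int = 0,
    threshold: float = 0.5,
    classifier_params: Mapping | None = None,
) -> dict:
    """Stratified k-fold evaluation; returns per-fold and mean/std metrics.

    The report carries the full configuration snapshot (classifier,
    seeds, threshold) so any run can be reproduced exactly.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for fold_id, (train_idx, test_idx) in enumerate(skf.split(features, labels)):
        model = make_classifier(classifier, seed, **dict(classifier_params or {}))
        model.fit(features[train_idx], labels[train_idx])
        scores = model.predict_proba(features[test_idx])[:, 1]
        metrics = compute_metrics(labels[test_idx], scores, threshold)
        folds.append({"fold": fold_id, "n_test": int(len(test_idx)), **metrics})
    mean = {m: float(np.mean([f[m] for f in folds])) for m in METRIC_NAMES}
    std = {m: float(np.std([f[m] for f in folds])) for m in METRIC_NAMES}
    return {
        "config": {
            "classifier": classifier,
            "classifier_params": dict(classifier_params or {}),
            "n_folds": n_folds,
            "seed": seed,
            "threshold": threshold,
        },
        "folds": folds,
        "mean": mean,
        "std": std,
    }


def rank_candidates(
    drug_id: str,
    model,
    table: AssociationTable,
    node_index: Mapping[str, int],
    H: np.ndarray,
    E: np.ndarray,
    mode: str = "fused",
    top_k: int = 10,
) -> list[tuple[str, float]]:
    """Score every unobserved disease for one drug; return the top k.

    Diseases already associated with the drug are excluded, scores come
    from the trained model's positive-class probability, and the output
    is sorted descending (ties broken by disease id for determinism).
    """
    if drug_id not in node_index:
        raise KeyError(f"unknown drug {drug_id!r}")
    known = {z for d, z in table.pairs if d == drug_id}
    candidates = [z for z in table.disease_ids if z not in known]
    if not candidates:
        return []
    F = fuse_features([(drug_id, z) for z in candidates], node_index, H, E, mode)
    scores = model.predict_proba(F)[:, 1]
    ranked = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    return [(z, float(s)) for z, s in ranked[:top_k]]


class MGRLClassifier(BaseEstimator, ClassifierMixin):
    """Pair classifier over fused representation features.

    A thin, seedable wrapper around the supported classifiers with the
    pipeline's defaults (Random Forest, 500 trees), exposing the
    standard fit / predict / predict_proba surface so it composes with
    sklearn model selection.
    """

    def __init__(self, classifier: str = "rf", random_state: int = 0, **params):
        self.classifier = classifier
        self.random_state = random_state
        self._params = params

    def get_params(self, deep=True):
        return {
            "classifier": self.classifier,
            "random_state": self.random_state,
            **self._params,
        }

    def set_params(self, **params):
        self.classifier = params.pop("classifier", self.classifier)
        self.random_state = params.pop("random_state", self.random_state)
        self._params.update(params)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int)
        self.model_ = make_classifier(self.classifier, self.random_state, **self._params)
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=np.float64))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=np.float64))
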