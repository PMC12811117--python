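"""Link prediction on concatenated node embeddings.

An (anchor disease, partner) pair is featurized by concatenating the two
embedding vectors (anchor first, length 2J) and labelled 1/0 from curated
positive/negative partner lists.  Three classifier families — random
forest, SVM, and a feed-forward neural network — are compared under
stratified five-fold cross-validation, selected by accuracy
(TP+TN)/(TP+TN+FP+FN), and the winner ranks unlabeled partners by
predicted probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FAMILIES = ("random_forest", "svm", "ann")
#: tie-break preference when accuracies are equal
FAMILY_PRIORITY = ("svm", "random_forest", "ann")

#: small published-default hyperparameter grids, searched on training folds only
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "clf__n_estimators": [100, 300],
        "clf__max_depth": [None, 8],
    },
    "svm": {
        "clf__C": [0.1, 1.0, 10.0],
        "clf__gamma": ["scale"],
    },
    "ann": {
        "clf__hidden_layer_sizes": [(64,)],
        "clf__alpha": [1e-4, 1e-2],
    },
}


def concatenate_pair(anchor: np.ndarray, partner: np.ndarray) -> np.ndarray:
    """Anchor-first concatenation, length 2J."""
    anchor = np.asarray(anchor, dtype=float)
    partner = np.asarray(partner, dtype=float)
    if anchor.shape != partner.shape or anchor.ndim != 1:
        raise ValueError("anchor and partner embeddings must be 1-D and equal length")
    return np.concatenate([anchor, partner])


@dataclass
class LabeledPairSet:
    """Concatenated (anchor, partner) embeddings with 0/1 labels."""

    anchor_id: str
    partner_ids: list[str]
    features: np.ndarray  # (n_pairs, 2J)
    labels: np.ndarray    # (n_pairs,) int 0/1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        if len(self.partner_ids) != len(set(self.partner_ids)):
            raise ValueError("a partner appears twice in the pair set")
        if self.features.shape[0] != len(self.partner_ids) or len(self.labels) != len(self.partner_ids):
            raise ValueError("features/labels/partners misaligned")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if self.features.shape[1] % 2 != 0:
            raise ValueError("feature length must be 2J")


def assign_labels(
    partners: Sequence[str],
    positive_set: Iterable[str],
    negative_set: Iterable[str],
) -> tuple[list[tuple[str, int]], list[str]]:
    """Label partners 1 (positive), 0 (negative); the rest go to the
    unlabeled pool and never enter training."""
    positive_set, negative_set = set(positive_set), set(negative_set)
    overlap = positive_set & negative_set
    if overlap:
        raise ValueError(f"positive and negative sets overlap: {sorted(overlap)[:5]}")
    labeled, unlabeled = [], []
    for p in partners:
        if p in positive_set:
            labeled.append((p, 1))
        elif p in negative_set:
            labeled.append((p, 0))
        else:
            unlabeled.append(p)
    return labeled, unlabeled


def build_pair_set(
    embeddings: Mapping[str, np.ndarray],
    anchor_id: str,
    labeled_partners: Sequence[tuple[str, int]],
) -> LabeledPairSet:
    anchor = np.asarray(embeddings[anchor_id], dtype=float)
    pids = [p for p, _ in labeled_partners]
    X = np.stack([concatenate_pair(anchor, np.asarray(embeddings[p])) for p in pids])
    y = np.array([lab for _, lab in labeled_partners], dtype=int)
    return LabeledPairSet(anchor_id, pids, X, y)


@dataclass
class EvalReport:
    """Pooled out-of-fold confusion counts and derived metrics."""

    family: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc_roc: float
    fold_assignments: np.ndarray = field(repr=False)
    oof_probabilities: np.ndarray = field(repr=False)
    seed: int = 0

    @staticmethod
    def from_predictions(family, y_true, proba, folds, seed) -> "EvalReport":
        y_true = np.asarray(y_true, dtype=int)
        pred = (np.asarray(proba) >= 0.5).astype(int)
        tp = int(np.sum((pred == 1) & (y_true == 1)))
        tn = int(np.sum((pred == 0) & (y_true == 0)))
        fp = int(np.sum((pred == 1) & (y_true == 0)))
        fn = int(np.sum((pred == 0) & (y_true == 1)))
        total = tp + tn + fp + fn
        return EvalReport(
            family=family, tp=tp, tn=tn, fp=fp, fn=fn,
            accuracy=(tp + tn) / total,
            sensitivity=tp / (tp + fn) if tp + fn else 0.0,
            specificity=tn / (tn + fp) if tn + fp else 0.0,
            auc_roc=float(roc_auc_score(y_true, proba)),
            fold_assignments=np.asarray(folds),
            oof_probabilities=np.asarray(proba, dtype=float),
            seed=seed,
        )


def _make_estimator(family: str, seed: int) -> Pipeline:
    if family == "random_forest":
        clf = RandomForestClassifier(random_state=seed)
    elif family == "svm":
        # probability=True fits Platt scaling on the decision function so
        # ranking by probability is possible
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
    elif family == "ann":
        clf = MLPClassifier(max_iter=800, random_state=seed)
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def crossvalidate(
    pairs: LabeledPairSet,
    families: Sequence[str] = FAMILIES,
    k: int = 5,
    seed: int = 42,
    grids: Mapping[str, dict] | None = None,
) -> dict[str, EvalReport]:
    """Stratified k-fold evaluation of each classifier family.

    Hyperparameters are searched on the training folds only (an inner
    3-fold grid search); out-of-fold probabilities are pooled before
    computing the confusion counts, accuracy, sensitivity, specificity and
    AUC.
    """
    grids = dict(DEFAULT_GRIDS) | dict(grids or {})
    y = pairs.labels
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if n_pos < k or n_neg < k:
        raise ValueError(
            f"need >= {k} members per class for {k}-fold CV; got {n_pos} positive, {n_neg} negative"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(y), dtype=int)
    splits = list(skf.split(pairs.features, y))
    for fi, (_, test_idx) in enumerate(splits):
        fold_of[test_idx] = fi
    reports: dict[str, EvalReport] = {}
    for family in families:
        proba = np.empty(len(y))
        for train_idx, test_idx in splits:
            search = GridSearchCV(
                _make_estimator(family, seed), grids[family],
                cv=3, scoring="accuracy", n_jobs=1,
            )
            search.fit(pairs.features[train_idx], y[train_idx])
            proba[test_idx] = search.predict_proba(pairs.features[test_idx])[:, 1]
        reports[family] = EvalReport.from_predictions(family, y, proba, fold_of, seed)
    return reports


def select_best(reports: Mapping[str, EvalReport]) -> str:
    """Family with maximal accuracy; ties fall to svm > random_forest > ann."""
    if not reports:
        raise ValueError("no evaluation reports to select from")
    order = {f: i for i, f in enumerate(FAMILY_PRIORITY)}
    return max(
        reports,
        key=lambda f: (reports[f].accuracy, -order.get(f, len(order))),
    )


def fit_final_model(pairs: LabeledPairSet, family: str, seed: int = 42,
                    grids: Mapping[str, dict] | None = None):
    """Refit the chosen family on every labeled pair (grid-searched)."""
    grids = dict(DEFAULT_GRIDS) | dict(grids or {})
    search = GridSearchCV(
        _make_estimator(family, seed), grids[family], cv=3, scoring="accuracy", n_jobs=1
    )
    search.fit(pairs.features, pairs.labels)
    return search.best_estimator_


def rank_unlabeled(
    model,
    embeddings: Mapping[str, np.ndarray],
    anchor_id: str,
    unlabeled_partners: Sequence[str],
    top_k: int,
) -> list[tuple[str, float]]:
    """Rank unlabeled partners by predicted probability, descending;
    ties break lexicographically on partner id."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not unlabeled_partners:
        raise ValueError("unlabeled pool is empty")
    anchor = np.asarray(embeddings[anchor_id], dtype=float)
    X = np.stack([
        concatenate_pair(anchor, np.asarray(embeddings[p])) for p in unlabeled_partners
    ])
    proba = model.predict_proba(X)[:, 1]
    ranked = sorted(zip(unlabeled_partners, proba), key=lambda t: (-t[1], t[0]))
    return [(p, float(s)) for p, s in ranked[:top_k]]
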