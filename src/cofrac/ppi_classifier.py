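"""Supervised co-complex classification of candidate pairs.

A bagged ensemble of randomized decision trees (random forest) is trained on
the five co-elution features using gold-standard positive/negative pairs,
evaluated by pooled out-of-fold ROC/AUC with complex-level folds, and then
used to score every candidate pair; edges above a probability threshold form
the weighted interaction network. A regularized logistic model is available
as a simple baseline learner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from .errors import UsageError
from .pair_features import FEATURE_COLUMNS
from .reference_complexes import LabeledPairSet, Pair, canonical_pair

log = logging.getLogger(__name__)

MIN_CLASS_SIZE = 10


@dataclass
class TrainedModel:
    estimator: object
    feature_order: tuple[str, ...]
    n_positive: int
    n_negative: int
    seed: int
    learner: str

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        return proba[:, list(self.estimator.classes_).index(1)]


@dataclass
class EvaluationResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    y_true: np.ndarray
    y_score: np.ndarray
    n_folds_used: int


@dataclass
class ScoredNetwork:
    edges: pd.DataFrame  # protein_a, protein_b, probability (all candidates)
    threshold: float
    retained: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.retained = self.edges[
            self.edges["probability"] >= self.threshold
        ].reset_index(drop=True)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b, w in self.retained.itertuples(index=False):
            g.add_edge(a, b, weight=float(w))
        return g


def make_estimator(learner: str = "forest", n_trees: int = 500, seed: int = 0):
    if learner == "forest":
        return RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
    if learner == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise UsageError(f"unknown learner {learner!r}")


def feature_matrix(
    table: pd.DataFrame, pairs: Sequence[Pair] | None = None
) -> tuple[np.ndarray, list[Pair]]:
    """Extract the (pairs x 5) feature matrix in canonical feature order."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise UsageError(f"feature table lacks columns {missing}")
    indexed = table.set_index(
        [table["protein_a"].astype(str), table["protein_b"].astype(str)]
    )
    if pairs is None:
        pairs = list(indexed.index)
    X = indexed.loc[list(pairs), FEATURE_COLUMNS].to_numpy(dtype=float)
    return X, list(pairs)


def train(
    feature_table: pd.DataFrame,
    labels: LabeledPairSet,
    seed: int = 0,
    learner: str = "forest",
    n_trees: int = 500,
) -> TrainedModel:
    """Fit the classifier on labeled candidate pairs (deterministic per seed)."""
    available = {
        canonical_pair(a, b)
        for a, b in zip(feature_table["protein_a"], feature_table["protein_b"])
    }
    pos = sorted(labels.positives & available)
    neg = sorted(labels.negatives & available)
    if len(pos) < MIN_CLASS_SIZE or len(neg) < MIN_CLASS_SIZE:
        raise UsageError(
            f"need >= {MIN_CLASS_SIZE} positives and negatives with features; "
            f"got {len(pos)} / {len(neg)}"
        )
    X, _ = feature_matrix(feature_table, pos + neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    estimator = make_estimator(learner, n_trees, seed)
    estimator.fit(X, y)
    return TrainedModel(
        estimator=estimator,
        feature_order=tuple(FEATURE_COLUMNS),
        n_positive=len(pos),
        n_negative=len(neg),
        seed=seed,
        learner=learner,
    )


def pooled_roc(y_true: np.ndarray, y_score: np.ndarray) -> EvaluationResult:
    """ROC by threshold sweep and AUC by the trapezoid rule."""
    fpr, tpr, thr = roc_curve(y_true, y_score)
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    return EvaluationResult(
        auc=float(auc(fpr, tpr)),
        fpr=fpr,
        tpr=tpr,
        roc_thresholds=thr,
        precision=precision,
        recall=recall,
        y_true=np.asarray(y_true),
        y_score=np.asarray(y_score),
        n_folds_used=0,
    )


def evaluate(
    model: TrainedModel,
    feature_table: pd.DataFrame,
    labels: LabeledPairSet,
    pair_folds: Mapping[Pair, int],
) -> EvaluationResult:
    """Out-of-fold evaluation: retrain a clone per fold, pool predictions."""
    available = {
        canonical_pair(a, b)
        for a, b in zip(feature_table["protein_a"], feature_table["protein_b"])
    }
    labeled = [
        (p, 1) for p in sorted(labels.positives & available)
    ] + [(p, 0) for p in sorted(labels.negatives & available)]
    labeled = [(p, y) for p, y in labeled if p in pair_folds]
    if not labeled:
        raise UsageError("no labeled pairs with features and folds")
    folds = sorted({pair_folds[p] for p, _ in labeled})
    y_true_all, y_score_all = [], []
    used = 0
    for fold in folds:
        test = [(p, y) for p, y in labeled if pair_folds[p] == fold]
        train_set = [(p, y) for p, y in labeled if pair_folds[p] != fold]
        test_ys = {y for _, y in test}
        train_ys = {y for _, y in train_set}
        if len(test_ys) < 2 or len(train_ys) < 2:
            log.warning("fold %d skipped: single-class data", fold)
            continue
        X_train, _ = feature_matrix(feature_table, [p for p, _ in train_set])
        X_test, _ = feature_matrix(feature_table, [p for p, _ in test])
        est = clone(model.estimator)
        est.fit(X_train, [y for _, y in train_set])
        scores = est.predict_proba(X_test)[:, list(est.classes_).index(1)]
        y_true_all.extend(y for _, y in test)
        y_score_all.extend(scores)
        used += 1
    if used == 0:
        raise UsageError("all folds were single-class")
    result = pooled_roc(np.array(y_true_all), np.array(y_score_all))
    result.n_folds_used = used
    return result


def score_all(
    model: TrainedModel, feature_table: pd.DataFrame, threshold: float = 0.5
) -> ScoredNetwork:
    """Score every candidate pair; retain edges with probability >= threshold."""
    if tuple(model.feature_order) != tuple(FEATURE_COLUMNS):
        raise UsageError(
            f"model feature order {model.feature_order} does not match "
            f"{tuple(FEATURE_COLUMNS)}"
        )
    X, pairs = feature_matrix(feature_table)
    probs = model.predict_proba(X)
    edges = pd.DataFrame(
        {
            "protein_a": [p[0] for p in pairs],
            "protein_b": [p[1] for p in pairs],
            "probability": probs,
        }
    )
    return ScoredNetwork(edges=edges, threshold=threshold)


def precision_targeting_threshold(
    result: EvaluationResult, min_precision: float = 0.9
) -> float:
    """Smallest score threshold achieving the requested held-out precision."""
    order = np.argsort(-result.y_score)
    y = result.y_true[order]
    s = result.y_score[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    ok = np.nonzero(precision >= min_precision)[0]
    if ok.size == 0:
        warnings.warn("requested precision unattainable; returning max score")
        return float(s[0])
    return float(s[ok[-1]])
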