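"""Logistic-regression classifier separating IFN proteins from neighbours.

The workflow mirrors the model it implements: fit an L2-penalised logistic
regression on the full APAAC feature space, prune every feature whose
|coefficient| falls below the mean |coefficient|, refit on the survivors,
and report stratified 5-fold cross-validated precision/recall/F1/accuracy
and ROC-AUC.  Optimisation uses a stochastic average gradient (SAG) solver
to tolerance 1e-6; any deterministic convex solver reaching that tolerance
would produce the same model to numerical precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import (
    DegenerateLabelsError,
    EmptyEvalError,
    EmptyModelError,
    FeatureShapeError,
    StratificationError,
)

_SOLVER_TOL = 1e-6
_MAX_ITER = 20000


@dataclass
class LabeledDataset:
    """Feature matrix with boolean labels (True = type I IFN) and ids."""

    X: np.ndarray
    y: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.ids and len(self.ids) != len(self.y):
            raise ValueError("ids length differs from labels")

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        ids = tuple(self.ids[i] for i in indices) if self.ids else ()
        return LabeledDataset(self.X[indices], self.y[indices], ids)


@dataclass
class ScopeModel:
    """Trained classifier: coefficients over selected features plus metadata.

    ``selected`` masks the original feature indices; ``coefficients`` has
    one entry per True in the mask.  The decision threshold applies to the
    positive-class probability.
    """

    coefficients: np.ndarray
    intercept: float
    selected: np.ndarray
    threshold: float = 0.5
    seed: int = 0
    metadata: dict = field(default_factory=dict)
    #: per-selected-feature standardisation applied before the linear map;
    #: APAAC components live on a ~1/dimension scale, so coefficients are
    #: learned (and pruned) in standardised space
    feature_means: np.ndarray | None = None
    feature_scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        n = self.coefficients.shape[0]
        if n != int(self.selected.sum()):
            raise ValueError("coefficient count must equal selected-feature count")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly inside (0, 1)")
        if self.feature_means is None:
            self.feature_means = np.zeros(n)
        if self.feature_scales is None:
            self.feature_scales = np.ones(n)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_scales = np.asarray(self.feature_scales, dtype=float)

    @property
    def n_features_original(self) -> int:
        return self.selected.shape[0]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_original:
            raise FeatureShapeError(
                f"expected {self.n_features_original} features, got {X.shape[1]}"
            )
        Z = (X[:, self.selected] - self.feature_means) / self.feature_scales
        return Z @ self.coefficients + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision_scores(X)
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self) -> str:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "selected": self.selected.astype(int).tolist(),
            "threshold": self.threshold,
            "seed": self.seed,
            "metadata": self.metadata,
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScopeModel":
        payload = json.loads(text)
        return cls(
            coefficients=np.array(payload["coefficients"]),
            intercept=float(payload["intercept"]),
            selected=np.array(payload["selected"], dtype=bool),
            threshold=float(payload["threshold"]),
            seed=int(payload["seed"]),
            metadata=payload.get("metadata", {}),
            feature_means=np.array(payload["feature_means"]),
            feature_scales=np.array(payload["feature_scales"]),
        )


@dataclass
class EvalReport:
    """Confusion counts plus the derived metrics, all recomputable."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float
    flags: tuple[str, ...] = ()
    per_fold: tuple["EvalReport", ...] = ()

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int, auc: float, flags=()) -> "EvalReport":
        flags = tuple(flags)
        if tp + fp == 0:
            precision, flags = 0.0, flags + ("undefined_precision",)
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        accuracy = (tp + tn) / (tp + fp + tn + fn)
        return cls(tp, fp, tn, fn, precision, recall, f1, accuracy, auc, flags)


def fit_logistic(
    dataset: LabeledDataset,
    l2_strength: float = 1.0,
    seed: int = 0,
    class_weight: str | dict | None = None,
) -> ScopeModel:
    """Fit an L2-penalised logistic regression on all features (SAG solver).

    Deterministic for a fixed seed; non-convergence at the iteration cap is
    recorded in model metadata rather than raised.  ``class_weight`` is off
    by default (the IFN/neighbour imbalance is left as-is); pass
    ``"balanced"`` or an explicit mapping to reweight.
    """
    classes = np.unique(dataset.y)
    if classes.size < 2:
        raise DegenerateLabelsError("training data contains a single class")
    # standardise features before fitting: the SAG solver needs comparably
    # scaled inputs, and the pruning rule then compares coefficients on a
    # common scale
    means = dataset.X.mean(axis=0)
    scales = dataset.X.std(axis=0)
    scales[scales == 0] = 1.0
    Z = (dataset.X - means) / scales
    clf = LogisticRegression(
        C=1.0 / l2_strength,
        solver="sag",
        tol=_SOLVER_TOL,
        max_iter=_MAX_ITER,
        random_state=seed,
        class_weight=class_weight,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            clf.fit(Z, dataset.y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(Z, dataset.y)
    return ScopeModel(
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        selected=np.ones(dataset.X.shape[1], dtype=bool),
        seed=seed,
        metadata={
            "l2_strength": l2_strength,
            "converged": converged,
            "n_features_in": int(dataset.X.shape[1]),
        },
        feature_means=means,
        feature_scales=scales,
    )


def select_features(model: ScopeModel) -> np.ndarray:
    """Mean-|coefficient| pruning mask over the model's feature space.

    A feature survives iff |ω_u| ≥ mean(|ω|); the boundary uses ≥ so equal
    coefficients all survive.  The mean is taken over absolute values — a
    signed mean could be negative and make the rule vacuous.
    """
    magnitudes = np.abs(model.coefficients)
    if not magnitudes.any():
        raise EmptyModelError("all coefficients are zero; nothing to select")
    return magnitudes >= magnitudes.mean()


def train_scope(
    dataset: LabeledDataset,
    l2_strength: float = 1.0,
    seed: int = 0,
    prune: bool = True,
    class_weight: str | dict | None = None,
) -> ScopeModel:
    """Full training workflow: fit on all features, prune, refit on survivors."""
    full = fit_logistic(dataset, l2_strength=l2_strength, seed=seed, class_weight=class_weight)
    if not prune:
        return full
    mask = select_features(full)
    reduced = LabeledDataset(dataset.X[:, mask], dataset.y, dataset.ids)
    refit = fit_logistic(reduced, l2_strength=l2_strength, seed=seed, class_weight=class_weight)
    return ScopeModel(
        coefficients=refit.coefficients,
        intercept=refit.intercept,
        selected=mask,
        threshold=full.threshold,
        seed=seed,
        metadata={
            **refit.metadata,
            "n_features_in": int(dataset.X.shape[1]),
            "n_features_selected": int(mask.sum()),
            "pre_pruning_dimension": int(dataset.X.shape[1]),
            "post_pruning_dimension": int(mask.sum()),
        },
        feature_means=refit.feature_means,
        feature_scales=refit.feature_scales,
    )


def evaluate(
    labels: Sequence[bool],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> EvalReport:
    """Confusion counts at ``threshold`` plus precision/recall/F1/accuracy/AUC.

    AUC is the area under the ROC curve swept over all score thresholds
    with ties credited 0.5 (the Mann–Whitney statistic); it is NaN with a
    flag when only one class is present.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise EmptyEvalError("no examples to evaluate")
    if labels.size != scores.size:
        raise ValueError("labels and scores lengths differ")
    predicted = scores >= threshold
    tp = int(np.sum(predicted & labels))
    fp = int(np.sum(predicted & ~labels))
    tn = int(np.sum(~predicted & ~labels))
    fn = int(np.sum(~predicted & labels))
    flags: tuple[str, ...] = ()
    if labels.all() or not labels.any():
        auc, flags = float("nan"), ("single_class_auc",)
    else:
        auc = float(roc_auc_score(labels, scores))
    return EvalReport.from_counts(tp, fp, tn, fn, auc, flags)


def cross_validate(
    dataset: LabeledDataset,
    folds: int = 5,
    seed: int = 0,
    l2_strength: float = 1.0,
    prune: bool = True,
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full train-prune-refit flow.

    Fold assignment is seeded and deterministic.  The top-level report pools
    confusion counts across folds (metrics recomputed from the pooled
    counts); AUC is the mean of per-fold AUCs; per-fold reports ride along.
    """
    counts = np.bincount(dataset.y.astype(int), minlength=2)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members < {folds} folds"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_reports = []
    for train_idx, test_idx in splitter.split(dataset.X, dataset.y):
        model = train_scope(
            dataset.subset(train_idx), l2_strength=l2_strength, seed=seed, prune=prune
        )
        probs = model.predict_proba(dataset.X[test_idx])
        fold_reports.append(evaluate(dataset.y[test_idx], probs, threshold))
    pooled = EvalReport.from_counts(
        tp=sum(r.tp for r in fold_reports),
        fp=sum(r.fp for r in fold_reports),
        tn=sum(r.tn for r in fold_reports),
        fn=sum(r.fn for r in fold_reports),
        auc=float(np.mean([r.auc for r in fold_reports])),
    )
    pooled.per_fold = tuple(fold_reports)
    return pooled


def predict(
    model: ScopeModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and positive-class probabilities for a feature matrix."""
    probs = model.predict_proba(X)
    return probs >= model.threshold, probs
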