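"""Balanced random-forest eligibility classifier.

Training sets in screening are heavily imbalanced (eligible abstracts are
~5% of the corpus), so the minority class is rebalanced to 1:1 with SMOTE —
synthetic minority rows interpolated between a real minority sample and one
of its k minority-class nearest neighbours. Rebalancing happens strictly
inside each cross-validation training fold, never in the validation fold,
and the tuning criterion is mean cross-validated sensitivity (recall of the
eligible class) at a fixed decision threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .representations import DocVectors


class TrainingError(ValueError):
    pass


@dataclass
class TrainingSet:
    """Screened documents: latent-semantic features plus oracle decisions."""

    doc_ids: list[str]
    X: np.ndarray  # (n, D) svd-representation rows
    y: np.ndarray  # binary: 1 eligible, 0 ineligible

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.doc_ids) != len(self.y) or self.X.shape[0] != len(self.y):
            raise TrainingError("doc_ids, X and y must have equal length")

    @property
    def n(self) -> int:
        return len(self.y)

    def has_both_classes(self) -> bool:
        return 0 in self.y and 1 in self.y


@dataclass
class ClassifierSpec:
    """Hyper-parameters of the screening classifier."""

    n_trees: int = 500
    n_folds: int = 5
    tuning_grid: Optional[Sequence[int]] = None  # features per split; default from sqrt(D)
    smote_k: int = 5
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise TrainingError("n_folds must be >= 2")
        if not (0.0 < self.decision_threshold < 1.0):
            raise TrainingError("decision_threshold must lie in (0, 1)")

    def grid_for(self, D: int) -> list[int]:
        if self.tuning_grid:
            return sorted(set(int(g) for g in self.tuning_grid))
        root = math.sqrt(D)
        return sorted({max(1, round(root / 2)), max(1, round(root)), min(D, max(1, round(2 * root)))})


def smote_oversample(
    X_minority: np.ndarray,
    X_majority: np.ndarray,
    k: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rebalance to 1:1 by SMOTE interpolation within the minority class.

    Each synthetic row is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn a uniformly chosen one of x_i's k nearest minority neighbours.
    Returns (X, y, is_synthetic); real rows come first (majority then
    minority), synthetic rows last, so provenance is recoverable.
    """
    X_min = np.asarray(X_minority, dtype=float)
    X_maj = np.asarray(X_majority, dtype=float)
    n_min, n_maj = len(X_min), len(X_maj)
    if n_min < 2:
        raise TrainingError("SMOTE needs at least 2 minority samples to interpolate")
    if k > n_min - 1:
        warnings.warn(f"smote_k={k} exceeds minority size - 1; clamping to {n_min - 1}")
        k = n_min - 1
    rng = np.random.default_rng(seed)
    n_new = max(0, n_maj - n_min)
    synth = np.empty((n_new, X_min.shape[1]))
    if n_new:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself
        base = rng.integers(0, n_min, size=n_new)
        pick = rng.integers(1, k + 1, size=n_new)
        u = rng.uniform(0.0, 1.0, size=n_new)
        for t in range(n_new):
            i = base[t]
            j = neigh[i, pick[t]]
            synth[t] = X_min[i] + u[t] * (X_min[j] - X_min[i])
    X = np.vstack([X_maj, X_min, synth])
    y = np.concatenate([np.zeros(n_maj, dtype=int), np.ones(n_min + n_new, dtype=int)])
    is_synthetic = np.concatenate([np.zeros(n_maj + n_min, dtype=bool), np.ones(n_new, dtype=bool)])
    return X, y, is_synthetic


@dataclass
class FittedClassifier:
    model: RandomForestClassifier
    spec: ClassifierSpec
    chosen_mtry: int
    cv_sensitivity: float
    n_features: int
    cv_details: dict = field(default_factory=dict)

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        proba = self.model.predict_proba(np.asarray(X, dtype=float))
        pos = list(self.model.classes_).index(1)
        return proba[:, pos]


def _fold_sensitivity(proba: np.ndarray, y_true: np.ndarray, threshold: float) -> float:
    pos = y_true == 1
    if not pos.any():
        return float("nan")
    return float((proba[pos] >= threshold).mean())


def train_rf_cv(train: TrainingSet, spec: ClassifierSpec) -> FittedClassifier:
    """Fit the screening random forest with sensitivity-maximizing CV tuning.

    For each candidate features-per-split value, stratified n-fold CV is run
    with SMOTE applied only inside each training fold; the value with the
    highest mean validation-fold sensitivity wins (ties go to the smaller
    value). The final model is refit on the full SMOTE-balanced training set.
    """
    if not train.has_both_classes():
        raise TrainingError(
            "training set has a single class; screen more documents (phase 1) before fitting"
        )
    if train.n < 2 * spec.n_folds:
        raise TrainingError(f"need at least {2 * spec.n_folds} training rows, have {train.n}")
    D = train.X.shape[1]
    grid = spec.grid_for(D)
    n_pos = int(train.y.sum())
    n_folds = min(spec.n_folds, n_pos) if n_pos >= 2 else spec.n_folds
    if n_folds < spec.n_folds:
        warnings.warn(f"only {n_pos} eligible rows; using {n_folds}-fold CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(train.X, train.y))
    details: dict = {"grid": grid, "fold_val_indices": [list(map(int, v)) for _, v in folds],
                     "mean_sensitivity": {}, "synthetic_in_validation": 0}
    best_m, best_sens = None, -1.0
    for m in grid:
        sens_per_fold = []
        for tr_idx, va_idx in folds:
            X_tr, y_tr = train.X[tr_idx], train.y[tr_idx]
            if y_tr.sum() < 2 or y_tr.sum() == len(y_tr):
                continue
            Xb, yb, _ = smote_oversample(X_tr[y_tr == 1], X_tr[y_tr == 0], spec.smote_k, spec.seed)
            rf = RandomForestClassifier(
                n_estimators=spec.n_trees, max_features=min(m, D),
                random_state=spec.seed, n_jobs=1,
            ).fit(Xb, yb)
            pos = list(rf.classes_).index(1)
            proba = rf.predict_proba(train.X[va_idx])[:, pos]
            s = _fold_sensitivity(proba, train.y[va_idx], spec.decision_threshold)
            if not math.isnan(s):
                sens_per_fold.append(s)
        mean_sens = float(np.mean(sens_per_fold)) if sens_per_fold else 0.0
        details["mean_sensitivity"][m] = mean_sens
        if mean_sens > best_sens + 1e-12:  # strict improvement; ties keep the smaller m
            best_m, best_sens = m, mean_sens
    Xb, yb, _ = smote_oversample(
        train.X[train.y == 1], train.X[train.y == 0], spec.smote_k, spec.seed
    )
    final = RandomForestClassifier(
        n_estimators=spec.n_trees, max_features=min(best_m, D), random_state=spec.seed, n_jobs=1
    ).fit(Xb, yb)
    return FittedClassifier(
        model=final, spec=spec, chosen_mtry=int(best_m),
        cv_sensitivity=float(best_sens), n_features=D, cv_details=details,
    )


def predict_eligible(
    fitted: FittedClassifier, vectors: DocVectors, threshold: Optional[float] = None
) -> set[str]:
    """Documents whose predicted eligibility probability reaches the threshold.

    Scores every corpus document, screened or not; callers filter
    already-screened ids.
    """
    if vectors.kind != "svd":
        raise TrainingError(f"classifier predicts on svd vectors, got kind={vectors.kind!r}")
    if vectors.dims != fitted.n_features:
        raise TrainingError(
            f"dimension mismatch: model fitted on {fitted.n_features} features, vectors have {vectors.dims}"
        )
    thr = fitted.spec.decision_threshold if threshold is None else threshold
    proba = fitted.probabilities(vectors.matrix)
    return {d for d, p in zip(vectors.doc_ids, proba) if p >= thr}
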