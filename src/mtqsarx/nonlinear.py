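"""Non-linear classifiers: grid-searched or user-specified hyperparameters,
plus applicability-domain flagging by prediction confidence.

Six learners are supported (kNN, Bernoulli naive Bayes, SVC, random forest,
gradient boosting, MLP). Grid search is an exhaustive, deterministic
evaluation of the Cartesian product of a parameter grid by stratified
n-fold cross-validated accuracy (or AUROC), ties resolved in favour of the
first combination in grid order.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "LEARNERS",
    "GridSpec",
    "FittedClassifier",
    "load_grid",
    "default_grid",
    "grid_search",
    "fit_user",
    "predict_with_confidence",
]

LEARNERS = ("knn", "nb", "svc", "rf", "gb", "mlp")

_FACTORIES = {
    "knn": KNeighborsClassifier,
    "nb": BernoulliNB,
    "svc": SVC,
    "rf": RandomForestClassifier,
    "gb": GradientBoostingClassifier,
    "mlp": MLPClassifier,
}

# learners whose constructor takes random_state
_SEEDABLE = {"svc", "rf", "gb", "mlp"}

_GRID_FILES = {
    "knn": "grid_knn.csv",
    "nb": "grid_nb.csv",
    "svc": "grid_svc.csv",
    "rf": "grid_rf.csv",
    "gb": "grid_gb.csv",
    "mlp": "grid_mlp.csv",
}


def make_learner(learner: str, params: dict, seed: Optional[int] = None):
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; choose from {LEARNERS}")
    kwargs = dict(params)
    if learner == "svc":
        kwargs.setdefault("probability", True)
    if seed is not None and learner in _SEEDABLE:
        kwargs.setdefault("random_state", seed)
    try:
        est = _FACTORIES[learner](**kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid parameter for {learner!r}: {exc}") from exc
    return est


def _coerce(token: str):
    token = token.strip()
    if token == "None":
        return None
    if token == "True":
        return True
    if token == "False":
        return False
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        pass
    return token


def load_grid(path) -> dict:
    """Parse a grid CSV: each row is ``parameter,value1,value2,...``."""
    grid: dict = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            row = [c for c in row if c.strip() != ""]
            if not row:
                continue
            name, *values = row
            if not values:
                raise ValueError(f"parameter {name!r} has no values")
            grid[name.strip()] = [_coerce(v) for v in values]
    if not grid:
        raise ValueError(f"empty grid file: {path}")
    return grid


def default_grid(learner: str) -> dict:
    """Built-in grid shipped with the package for each learner."""
    if learner not in _GRID_FILES:
        raise ValueError(f"no default grid for learner {learner!r}")
    ref = resources.files("mtqsarx.grids") / _GRID_FILES[learner]
    with resources.as_file(ref) as path:
        return load_grid(path)


@dataclass
class GridSpec:
    learner: str
    grid: dict
    cv_folds: int = 5
    seed: Optional[int] = None
    scoring: str = "accuracy"

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")
        if not self.grid:
            raise ValueError("grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.scoring not in ("accuracy", "auroc"):
            raise ValueError("scoring must be 'accuracy' or 'auroc'")

    def combinations(self):
        """Cartesian product in grid order (first key varies slowest)."""
        names = list(self.grid)
        for values in itertools.product(*(self.grid[n] for n in names)):
            yield dict(zip(names, values))


@dataclass
class FittedClassifier:
    learner: str
    params: dict
    estimator: object
    cv_accuracy: float            # % on the sub-training set
    provenance: dict = field(default_factory=dict)


def _cv_accuracy(est, X: np.ndarray, y: np.ndarray, cv_folds: int,
                 seed: Optional[int], scoring: str = "accuracy") -> float:
    classes, counts = np.unique(y, return_counts=True)
    if cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds the minority-class count {counts.min()}")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=seed is not None,
                          random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        model = clone(est)
        model.fit(X[tr], y[tr])
        if scoring == "accuracy":
            scores.append(float((model.predict(X[te]) == y[te]).mean()))
        else:
            proba = model.predict_proba(X[te])[:, list(model.classes_).index(1)]
            scores.append(float(roc_auc_score(y[te], proba)))
    return float(np.mean(scores))


def grid_search(X, y, spec: GridSpec) -> FittedClassifier:
    """Exhaustive grid evaluation; the best combination (ties: first in grid
    order) is refit on the full sub-training set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    best_params, best_score = None, -np.inf
    table = []
    for params in spec.combinations():
        est = make_learner(spec.learner, params, seed=spec.seed)
        score = _cv_accuracy(est, X, y, spec.cv_folds, spec.seed, spec.scoring)
        table.append({**params, "cv_score": score})
        if score > best_score + 1e-12:
            best_params, best_score = params, score
    final = make_learner(spec.learner, best_params, seed=spec.seed)
    final.fit(X, y)
    cv_acc = best_score if spec.scoring == "accuracy" else _cv_accuracy(
        make_learner(spec.learner, best_params, seed=spec.seed),
        X, y, spec.cv_folds, spec.seed, "accuracy")
    return FittedClassifier(
        learner=spec.learner,
        params=dict(best_params),
        estimator=final,
        cv_accuracy=100.0 * cv_acc,
        provenance={"mode": "grid", "cv_folds": spec.cv_folds, "seed": spec.seed,
                    "scoring": spec.scoring, "n_combinations": len(table),
                    "search_table": table},
    )


def fit_user(X, y, learner: str, params: dict | None = None, *,
             cv_folds: int = 5, seed: Optional[int] = None) -> FittedClassifier:
    """Single fit with user-specified parameters plus an n-fold CV report."""
    params = dict(params or {})
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    est = make_learner(learner, params, seed=seed)
    cv_acc = _cv_accuracy(est, X, y, cv_folds, seed)
    est.fit(X, y)
    return FittedClassifier(
        learner=learner, params=params, estimator=est,
        cv_accuracy=100.0 * cv_acc,
        provenance={"mode": "user", "cv_folds": cv_folds, "seed": seed,
                    "defaults_used": not params},
    )


def predict_with_confidence(model: FittedClassifier, X,
                            confidence_threshold: float = 0.7):
    """Predict labels with a per-row confidence (class-membership score of
    the predicted class) and an in-applicability-domain flag
    (confidence >= threshold)."""
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError("confidence_threshold must lie in [0, 1]")
    est = model.estimator
    if not hasattr(est, "predict_proba"):
        raise ValueError(
            f"learner {model.learner!r} exposes no class-membership scores; "
            f"enable probability estimates (e.g. SVC(probability=True))")
    X = np.asarray(X, dtype=float)
    try:
        proba = est.predict_proba(X)
    except AttributeError as exc:      # SVC fitted without probability=True
        raise ValueError(
            "probability estimates are not enabled on this model; refit with "
            "probability support") from exc
    pred_idx = np.argmax(proba, axis=1)
    labels = est.classes_[pred_idx]
    confidence = proba[np.arange(len(proba)), pred_idx]
    in_ad = confidence >= confidence_threshold
    return labels, confidence, in_ad
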