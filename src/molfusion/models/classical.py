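"""Nine classical classifiers behind one train/score contract.

Families: SVC, RF, KNN, DT, GBDT, ABDT (AdaBoost over decision trees),
GNB, SGD, LR. Hyperparameters come either from a randomized search
(5-fold cross-validated AUC, 10 sampled configurations) over the shipped
search-space config, or are fixed by the caller.

Every trained model exposes a score in [0, 1] (class-1 probability where
the family provides one, otherwise a min-max calibrated decision value)
and a hard label at the fixed 0.5 operating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import yaml
from scipy.stats import loguniform, randint, uniform
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import RandomizedSearchCV
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

CLASSICAL_FAMILIES = ("SVC", "RF", "KNN", "DT", "GBDT", "ABDT", "GNB", "SGD", "LR")
ALL_FAMILIES = CLASSICAL_FAMILIES + ("FusionNet", "SmilesNet")

#: families whose fit is deterministic once hyperparameters are fixed
DETERMINISTIC_FAMILIES = ("ABDT", "GNB", "LR")


@dataclass
class ModelSpec:
    """A configured classifier: family, hyperparameters, seed."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ALL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; allowed: {ALL_FAMILIES}")


@dataclass
class PredictionSet:
    """Scored predictions of one model on one partition."""

    scores: np.ndarray
    model_id: str = ""
    partition_id: str = ""

    @property
    def labels(self) -> np.ndarray:
        return (self.scores >= 0.5).astype(int)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def build_estimator(family: str, hyperparameters: dict[str, Any], seed: int):
    """Instantiate the sklearn estimator for a family."""
    hp = dict(hyperparameters)
    if family == "SVC":
        return SVC(random_state=seed, **hp)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **hp)
    if family == "KNN":
        return KNeighborsClassifier(**hp)  # no randomness
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if family == "GBDT":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if family == "ABDT":
        return AdaBoostClassifier(random_state=seed, **hp)
    if family == "GNB":
        return GaussianNB(**hp)  # no randomness
    if family == "SGD":
        return SGDClassifier(random_state=seed, **hp)
    if family == "LR":
        hp.setdefault("solver", "lbfgs")
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=seed, **hp)
    raise ValueError(f"{family!r} is not a classical family")


def load_search_spaces() -> dict[str, dict]:
    """Shipped per-family hyperparameter search distributions."""
    text = resources.files("molfusion.data").joinpath("search_spaces.yaml").read_text()
    return yaml.safe_load(text)


def _materialize_space(space: dict) -> dict:
    """Turn the YAML encoding into sklearn-compatible distributions."""
    out = {}
    for name, spec in space.items():
        if isinstance(spec, dict):
            if "loguniform" in spec:
                lo, hi = spec["loguniform"]
                out[name] = loguniform(lo, hi)
            elif "uniform" in spec:
                lo, hi = spec["uniform"]
                out[name] = uniform(lo, hi - lo)
            elif "randint" in spec:
                lo, hi = spec["randint"]
                out[name] = randint(lo, hi)
            else:
                raise ValueError(f"unknown distribution spec for {name}: {spec}")
        else:
            out[name] = list(spec)
    return out


class TrainedModel:
    """Fitted estimator with the package's score/label contract."""

    def __init__(self, spec: ModelSpec, estimator, score_bounds=None):
        self.spec = spec
        self.estimator = estimator
        self._bounds = score_bounds  # (min, max) of training decision values

    def score(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        raw = est.decision_function(X)
        lo, hi = self._bounds
        if hi <= lo:
            return np.full(len(raw), 0.5)
        return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)

    def predict(self, X: np.ndarray) -> PredictionSet:
        return PredictionSet(self.score(X), model_id=self.spec.family)


def train_classical(spec: ModelSpec, features: np.ndarray,
                    labels: np.ndarray) -> TrainedModel:
    """Fit one classical classifier with fixed hyperparameters."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    est = build_estimator(spec.family, spec.hyperparameters, spec.seed)
    est.fit(features, labels)
    bounds = None
    if not hasattr(est, "predict_proba"):
        raw = est.decision_function(features)
        bounds = (float(raw.min()), float(raw.max()))
    return TrainedModel(spec, est, score_bounds=bounds)


def randomized_search(
    family: str,
    features: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    search_space: dict | None = None,
) -> tuple[ModelSpec, Any]:
    """Randomized hyperparameter search by 5-fold cross-validated AUC.

    Returns the best :class:`ModelSpec` and the full cv_results_ trial log.
    Families without a search space fall back to defaults with a warning.
    """
    if search_space is None:
        search_space = load_search_spaces().get(family)
    if not search_space:
        logger.warning("no search space for %s; using default hyperparameters", family)
        return ModelSpec(family, {}, seed), None
    space = _materialize_space(search_space)
    est = build_estimator(family, {}, seed)
    search = RandomizedSearchCV(
        est, space, n_iter=n_iter, cv=n_folds, scoring="roc_auc",
        random_state=seed, error_score=-np.inf, n_jobs=1,
    )
    search.fit(features, labels)
    best = {k: (v.item() if hasattr(v, "item") else v)
            for k, v in search.best_params_.items()}
    return ModelSpec(family, best, seed), search.cv_results_
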