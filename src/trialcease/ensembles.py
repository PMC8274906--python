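"""Undersampling ensembles of the four classifier families.

Class imbalance (completion trials dominate cessation trials roughly 4.36:1)
is handled by random undersampling of the majority class at a configurable
majority:minority ratio.  Because undersampling discards examples, it is
repeated (10 times by default), each repeat training one member model; the
ensemble prediction is the arithmetic mean of the members' positive-class
(cessation) probabilities.  When the requested ratio retains the whole
majority class no sampling happens and a single model is trained on the full
data — the "single model" baseline.

Member hyperparameters are fixed values from a nested 5-fold grid search:
neural net — one hidden layer of 50 logistic units, Adam, batch size 50, 50
epochs; random forest — 1500 trees, no bootstrap, entropy criterion,
min_samples_split 5, min_samples_leaf 2; gradient-boosted trees — 600 trees,
min loss reduction 2, max depth 5, min child weight 1, feature subsampling
0.6, no row subsampling; logistic regression — L2-penalized with C = 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

FAMILIES = ("neural_net", "random_forest", "gradient_boosted_trees", "logistic")

#: Original majority:minority imbalance of the reference cohort (628/144).
DEFAULT_RATIOS = (4.36, 4.0, 3.0, 2.0, 1.0, 0.9)


@dataclass
class SamplingConfig:
    """Undersampling ratio r (majority retained per minority example),
    number of sampling repeats and the base seed for repeat i = base_seed+i."""

    ratio: float = 1.0
    n_repeats: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError(f"sampling ratio must be > 0, got {self.ratio}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class EnsembleModel:
    family: str
    members: list
    sampling: SamplingConfig
    single_model: bool = False
    feature_names: list[str] | None = None


def undersample_majority(y, ratio: float, seed: int) -> np.ndarray:
    """Retained index set: all minority plus round(ratio*n_minority) majority.

    The minority class is label 1 (cessation).  Majority indices are sampled
    without replacement, capped at the majority size; every minority index is
    always retained.  Deterministic given the seed.
    """
    if ratio <= 0:
        raise ValueError(f"sampling ratio must be > 0, got {ratio}")
    y = np.asarray(y)
    minority_idx = np.flatnonzero(y == 1)
    majority_idx = np.flatnonzero(y != 1)
    if len(minority_idx) == 0 or len(majority_idx) == 0:
        raise ValueError("undersample_majority requires both classes present")
    n_keep = min(int(round(ratio * len(minority_idx))), len(majority_idx))
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority_idx, size=n_keep, replace=False)
    return np.sort(np.concatenate([minority_idx, kept_majority]))


def _make_estimator(family: str, seed: int, params: dict | None = None):
    params = dict(params or {})
    if family == "neural_net":
        defaults = dict(
            hidden_layer_sizes=(50,),
            activation="logistic",
            solver="adam",
            batch_size=50,
            max_iter=50,
            random_state=seed,
        )
    elif family == "random_forest":
        defaults = dict(
            n_estimators=1500,
            bootstrap=False,
            criterion="entropy",
            min_samples_split=5,
            min_samples_leaf=2,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    elif family == "gradient_boosted_trees":
        defaults = dict(
            n_estimators=600,
            gamma=2.0,
            max_depth=5,
            min_child_weight=1,
            colsample_bytree=0.6,
            subsample=1.0,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    elif family == "logistic":
        defaults = dict(penalty="l2", C=1.0, tol=1e-6, solver="lbfgs", max_iter=5000)
    else:
        raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    defaults.update(params)
    if family == "neural_net":
        return MLPClassifier(**defaults)
    if family == "random_forest":
        return RandomForestClassifier(**defaults)
    if family == "gradient_boosted_trees":
        return XGBClassifier(**defaults)
    return LogisticRegression(**defaults)


def train_member(family: str, X, y, seed: int, params: dict | None = None):
    """Fit one seeded member model exposing positive-class probabilities."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("train_member requires both classes in y")
    model = _make_estimator(family, seed, params)
    with warnings.catch_warnings():
        # The 50-epoch budget is a fixed hyperparameter, not a convergence
        # criterion, so the MLP convergence warning is expected noise.
        warnings.simplefilter("ignore")
        model.fit(np.asarray(X, dtype=float), y.astype(int))
    return model


def member_proba(model, X) -> np.ndarray:
    """Positive-class probability column of a fitted member."""
    proba = model.predict_proba(np.asarray(X, dtype=float))
    positive_col = list(model.classes_).index(1)
    return proba[:, positive_col]


def train_ensemble(
    family: str,
    X,
    y,
    sampling: SamplingConfig,
    params: dict | None = None,
    feature_names: list[str] | None = None,
) -> EnsembleModel:
    """Train the repeated-undersampling ensemble.

    Repeat i uses seed ``base_seed + i`` for both the sampling draw and the
    member initialization.  If the ratio retains the entire majority class,
    sampling is skipped and a single member is trained on the full data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_min = int((y == 1).sum())
    n_maj = int((y != 1).sum())
    if n_min == 0 or n_maj == 0:
        raise ValueError("train_ensemble requires both classes present")
    no_sampling = int(round(sampling.ratio * n_min)) >= n_maj
    if no_sampling:
        members = [train_member(family, X, y, sampling.base_seed, params)]
        return EnsembleModel(family, members, sampling, True, feature_names)
    members = []
    for i in range(sampling.n_repeats):
        seed = sampling.base_seed + i
        idx = undersample_majority(y, sampling.ratio, seed)
        members.append(train_member(family, X[idx], y[idx], seed, params))
    return EnsembleModel(family, members, sampling, False, feature_names)


def predict_proba(ensemble: EnsembleModel, X) -> np.ndarray:
    """Mean positive-class probability over ensemble members."""
    X = np.asarray(X, dtype=float)
    if ensemble.feature_names is not None and X.shape[1] != len(ensemble.feature_names):
        raise ValueError(
            f"feature-count mismatch: model expects {len(ensemble.feature_names)} "
            f"columns, got {X.shape[1]}"
        )
    return np.mean([member_proba(m, X) for m in ensemble.members], axis=0)


def predict_label(ensemble: EnsembleModel, X, threshold: float = 0.5) -> np.ndarray:
    """Thresholded class labels (probability >= threshold -> cessation)."""
    return (predict_proba(ensemble, X) >= threshold).astype(int)
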