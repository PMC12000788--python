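"""Per-message binary classifiers: splits, balancing, tuning, prediction.

Three tree-ensemble families are supported behind the ``family`` knob:
``rf`` (bagged decision trees), ``lgbm`` (leaf-wise histogram gradient
boosting) and ``catboost`` (classic gradient boosting; the pre-installed
stack carries no ordered-boosting implementation, so this family is a
stand-in with the same role in the protocol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .evaluation import auprc

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("rf", "lgbm", "catboost")
BALANCING_METHODS = ("none", "random_oversampling", "smote")


@dataclass(frozen=True)
class SplitSpec:
    """How to divide advice samples into train and test."""

    mode: str = "dependent"  # dependent | independent
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.mode not in ("dependent", "independent"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")


@dataclass
class ModelConfig:
    family: str = "rf"
    balancing: str = "none"
    n_search: int = 100
    cv_folds: int = 5
    seeds: tuple[int, ...] = tuple(range(10))
    smote_k: int = 5
    param_grid: dict | None = None

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.balancing not in BALANCING_METHODS:
            raise ValueError(f"unknown balancing {self.balancing!r}")
        if not self.seeds:
            raise ValueError("seeds must be nonempty")


def split(
    samples: pd.DataFrame,
    spec: SplitSpec,
    participants: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split advice samples per the protocol.

    Dependent mode: per participant, the chronologically first 70% of samples
    train; fractional counts floor toward training.  Independent mode: the
    first 70% of participants by enrollment order train; participant sets are
    disjoint.  The split is governed by the ordering keys, so input row order
    is irrelevant.
    """
    samples = samples.sort_values(["participant", "date"]).reset_index(drop=True)
    if spec.mode == "dependent":
        train_parts, test_parts = [], []
        for _, grp in samples.groupby("participant", sort=True):
            n = len(grp)
            n_test = int(np.floor((1 - spec.train_fraction) * n))
            n_train = n - n_test
            train_parts.append(grp.iloc[:n_train])
            test_parts.append(grp.iloc[n_train:])
        return (
            pd.concat(train_parts, ignore_index=True),
            pd.concat(test_parts, ignore_index=True),
        )
    if participants is None:
        raise ValueError("independent split needs the participants table (enroll_order)")
    order = participants.sort_values("enroll_order")["participant"].tolist()
    order = [p for p in order if p in set(samples["participant"])]
    n = len(order)
    n_test = int(np.floor((1 - spec.train_fraction) * n))
    train_ids = set(order[: n - n_test])
    train = samples[samples["participant"].isin(train_ids)].reset_index(drop=True)
    test = samples[~samples["participant"].isin(train_ids)].reset_index(drop=True)
    return train, test


def random_oversample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority rows with replacement until classes are equal."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y
    idx = np.flatnonzero(y == minority)
    extra = rng.choice(idx, size=deficit, replace=True)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


def smote(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize classes with synthetic minority points.

    Each synthetic row is a convex combination of a minority point and one of
    its k nearest minority neighbors (Euclidean).  ``k`` is reduced when the
    minority class is small; a single minority point falls back to random
    oversampling.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y
    idx = np.flatnonzero(y == minority)
    if len(idx) == 1:
        logger.warning("single minority sample; falling back to random oversampling")
        return random_oversample(X, y, rng)
    if len(idx) <= k:
        logger.warning("minority count %d <= k=%d; reducing k", len(idx), k)
        k = len(idx) - 1
    Xm = X[idx]
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbors = np.argsort(d2, axis=1)[:, :k]
    base = rng.integers(0, len(idx), size=deficit)
    nn = neighbors[base, rng.integers(0, k, size=deficit)]
    lam = rng.random(deficit)[:, None]
    synth = Xm[base] + lam * (Xm[nn] - Xm[base])
    return np.vstack([X, synth]), np.concatenate([y, np.full(deficit, minority)])


def balance(
    X: np.ndarray, y: np.ndarray, method: str, seed: int, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a balancing method to a training set (never to test data)."""
    rng = np.random.default_rng(seed)
    if method == "none":
        return X, y
    if method == "random_oversampling":
        return random_oversample(X, y, rng)
    if method == "smote":
        return smote(X, y, rng, k=k)
    raise ValueError(f"unknown balancing method {method!r}")


DEFAULT_GRIDS = {
    "rf": {
        "n_estimators": [50, 100, 200],
        "max_depth": [3, 5, 8, None],
        "max_features": ["sqrt", 0.3, 0.6],
        "min_samples_leaf": [1, 2, 4],
        "class_weight": [None, "balanced"],
    },
    "lgbm": {
        "max_iter": [50, 100, 200],
        "learning_rate": [0.02, 0.05, 0.1, 0.2],
        "max_leaf_nodes": [7, 15, 31],
        "max_depth": [3, 6, None],
        "min_samples_leaf": [2, 5, 10],
        "l2_regularization": [0.0, 0.1, 1.0],
    },
    "catboost": {
        "max_iter": [50, 100, 200],
        "learning_rate": [0.02, 0.05, 0.1, 0.2],
        "max_depth": [2, 3, 4, 6],
        "min_samples_leaf": [1, 2, 5],
        "l2_regularization": [0.0, 0.5, 3.0],
    },
}


def make_estimator(family: str, params: dict, seed: int):
    if family == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "lgbm":
        # leaf-wise growth: leaf-count limited, depth unconstrained by default
        return HistGradientBoostingClassifier(random_state=seed, **params)
    if family == "catboost":
        # symmetric-tree analog: depth-limited, leaf count unconstrained
        return HistGradientBoostingClassifier(
            random_state=seed, max_leaf_nodes=None, **params
        )
    raise ValueError(f"unknown family {family!r}")


def _sample_params(grid: dict, n: int, rng: np.random.Generator) -> list[dict]:
    seen, out = set(), []
    for _ in range(n * 4):
        params = {k: v[rng.integers(0, len(v))] for k, v in grid.items()}
        key = tuple(sorted((k, str(v)) for k, v in params.items()))
        if key not in seen:
            seen.add(key)
            out.append(params)
        if len(out) >= n:
            break
    return out


@dataclass
class FittedModel:
    """A tuned, refit classifier with its training schema."""

    estimator: object
    feature_names: list[str]
    family: str
    balancing: str
    seed: int
    best_params: dict
    cv_auprc: float
    history: list = field(default_factory=list)

    def predict_proba(self, samples: pd.DataFrame) -> np.ndarray:
        return predict_proba(self, samples)


def _fold_iterator(config: ModelConfig, mode: str, y, groups, seed: int):
    if mode == "independent":
        cv = StratifiedGroupKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(y)), y, groups))
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def tune_and_fit(
    train: pd.DataFrame,
    feature_cols: list[str],
    label_col: str,
    config: ModelConfig,
    seed: int,
    mode: str = "dependent",
) -> FittedModel:
    """Random-search tuning with stratified CV, then refit on the full
    (balanced) training set.

    The CV objective is mean validation AUPRC computed on original
    (unbalanced) folds; balancing touches training folds only.  In
    independent mode folds are additionally grouped by participant.  All
    randomness (parameter sampling, folds, balancing, estimators) derives
    from ``seed``.
    """
    X = train[feature_cols].to_numpy(dtype=float)
    y = train[label_col].to_numpy(dtype=int)
    groups = train["participant"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"{label_col}: training data has a single class")

    rng = np.random.default_rng(seed)
    grid = config.param_grid or DEFAULT_GRIDS[config.family]
    candidates = _sample_params(grid, config.n_search, rng)
    folds = _fold_iterator(config, mode, y, groups, seed)

    # resample once if a fold is single-class, then fail loudly
    if any(len(np.unique(y[va])) < 2 for _, va in folds):
        folds = _fold_iterator(config, mode, y, groups, seed + 104729)
        if any(len(np.unique(y[va])) < 2 for _, va in folds):
            raise ValueError(f"{label_col}: degenerate single-class CV fold")

    best_score, best_params = -np.inf, None
    history = []
    for params in candidates:
        scores = []
        for tr, va in folds:
            Xb, yb = balance(X[tr], y[tr], config.balancing, seed, k=config.smote_k)
            est = make_estimator(config.family, params, seed)
            est.fit(Xb, yb)
            proba = est.predict_proba(X[va])[:, list(est.classes_).index(1)]
            scores.append(auprc(y[va], proba))
        mean_score = float(np.mean(scores))
        history.append((params, mean_score))
        if mean_score > best_score:
            best_score, best_params = mean_score, params

    Xb, yb = balance(X, y, config.balancing, seed, k=config.smote_k)
    final = make_estimator(config.family, best_params, seed)
    final.fit(Xb, yb)
    return FittedModel(
        estimator=final,
        feature_names=list(feature_cols),
        family=config.family,
        balancing=config.balancing,
        seed=seed,
        best_params=best_params,
        cv_auprc=best_score,
        history=history,
    )


def predict_proba(model: FittedModel, samples: pd.DataFrame) -> np.ndarray:
    """Positive-class probabilities; validates the feature schema by name."""
    missing = [c for c in model.feature_names if c not in samples.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = samples[model.feature_names].to_numpy(dtype=float)
    est = model.estimator
    proba = est.predict_proba(X)[:, list(est.classes_).index(1)]
    if not np.isfinite(proba).all():
        raise ValueError("non-finite prediction scores")
    return proba
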