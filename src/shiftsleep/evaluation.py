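"""Model scoring: AUPRC, random baselines, Welch comparison, thresholded
ensemble metrics.

The AUPRC estimator is the step-wise average precision (sum of precision at
each positive-containing rank times the recall increment), not trapezoidal
interpolation — the two differ at small sample sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def auprc(labels, scores) -> float:
    """Average-precision AUPRC; ties broken by stable sort on descending score."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0 or len(np.unique(y)) < 2:
        return float("nan")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # tied scores form one threshold group (single PR point per distinct score)
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.concatenate([boundary, [len(y_sorted) - 1]])
    tp = np.cumsum(y_sorted)[ends]
    ranks = ends + 1.0
    precision = tp / ranks
    recall = tp / tp[-1]
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float((precision * d_recall).sum())


def random_baseline(labels, n_trials: int = 10, seed: int = 0) -> np.ndarray:
    """AUPRC of uniform-random probability predictions, one value per trial."""
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    return np.array([auprc(y, rng.random(len(y))) for _ in range(n_trials)])


def welch_test(model_values, baseline_values) -> tuple[float, float]:
    """One-sided Welch t-test of H1: mean(model) > mean(baseline).

    Zero variance in both samples with equal means yields (0, 0.5) by
    convention.
    """
    a = np.asarray(model_values, dtype=float)
    b = np.asarray(baseline_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.warning("zero variance in both samples with equal means; P=0.5")
            return 0.0, 0.5
        return (np.inf, 0.0) if a.mean() > b.mean() else (-np.inf, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def classification_metrics(labels, predictions) -> dict[str, float]:
    """Sensitivity, specificity, precision and F1 from binary predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return {"sensitivity": sens, "specificity": spec, "precision": prec, "f1": f1}


def always_positive_f1(prevalence: float) -> float:
    """F1 of predicting every sample positive: 2p / (1 + p)."""
    return 2 * prevalence / (1 + prevalence)


def f1_at_threshold(labels, scores, threshold: float) -> float:
    return classification_metrics(labels, np.asarray(scores) >= threshold)["f1"]


def optimize_threshold(
    train: pd.DataFrame,
    feature_cols: list[str],
    label_col: str,
    model,
    seed: int,
    mode: str = "dependent",
    cv_folds: int = 5,
    grid_size: int = 101,
) -> float:
    """CV-based F1-optimal decision threshold.

    The fitted model's hyperparameters are refit per fold on the training
    portion; out-of-fold scores are pooled and a ``grid_size``-point grid on
    [0, 1] is searched for the F1 maximizer (ties -> lowest threshold).
    """
    from .advice_models import balance, make_estimator, _fold_iterator, ModelConfig

    X = train[feature_cols].to_numpy(dtype=float)
    y = train[label_col].to_numpy(dtype=int)
    groups = train["participant"].to_numpy()
    cfg = ModelConfig(
        family=model.family, balancing=model.balancing, cv_folds=cv_folds,
        seeds=(seed,), n_search=1,
    )
    folds = _fold_iterator(cfg, mode, y, groups, seed)
    if any(len(np.unique(y[va])) < 2 for _, va in folds) and all(
        len(np.unique(y[va])) < 2 for _, va in folds
    ):
        raise ValueError("all CV folds are single-class; cannot optimize threshold")
    oof = np.full(len(y), np.nan)
    for tr, va in folds:
        if len(np.unique(y[tr])) < 2:
            continue
        Xb, yb = balance(X[tr], y[tr], model.balancing, seed)
        est = make_estimator(model.family, model.best_params, seed)
        est.fit(Xb, yb)
        oof[va] = est.predict_proba(X[va])[:, list(est.classes_).index(1)]
    mask = ~np.isnan(oof)
    grid = np.linspace(0.0, 1.0, grid_size)
    f1s = np.array(
        [classification_metrics(y[mask], oof[mask] >= t)["f1"] for t in grid]
    )
    f1s = np.nan_to_num(f1s, nan=-1.0)
    return float(grid[int(np.argmax(f1s))])  # argmax returns the lowest tie


def ensemble_predict(models, thresholds, samples: pd.DataFrame) -> np.ndarray:
    """Majority vote of exactly 9 thresholded classifiers."""
    if len(models) != 9 or len(thresholds) != 9:
        raise ValueError("ensemble requires exactly 9 voters")
    votes = np.zeros(len(samples), dtype=int)
    for model, threshold in zip(models, thresholds):
        votes += (model.predict_proba(samples) >= threshold).astype(int)
    return (votes >= 5).astype(int)


@dataclass
class MessageEvaluation:
    """Evaluation rows for one (message, split mode) pair."""

    message_id: int
    mode: str
    rows: pd.DataFrame  # per (family, balancing): AUPRC stats + Welch test
    best_family: str
    best_balancing: str
    baseline_auprcs: np.ndarray


def evaluate_configurations(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_cols: list[str],
    message_id: int,
    mode: str,
    families=("rf", "lgbm", "catboost"),
    balancings=("none", "random_oversampling", "smote"),
    seeds: tuple[int, ...] = tuple(range(10)),
    n_search: int = 100,
    baseline_trials: int = 10,
    baseline_seed: int = 0,
) -> MessageEvaluation:
    """Run the full AUPRC protocol for one message under one split mode.

    Tunes/trains each (family, balancing) configuration once per seed,
    scores test AUPRC, and compares each configuration's seed sample against
    the uniform-random baseline with a one-sided Welch t-test.
    """
    from .advice_models import ModelConfig, tune_and_fit

    label_col = f"label_{message_id}"
    y_test = test[label_col].to_numpy(dtype=int)
    baselines = random_baseline(y_test, n_trials=baseline_trials, seed=baseline_seed)

    rows = []
    for family in families:
        for balancing in balancings:
            aucs = []
            for seed in seeds:
                cfg = ModelConfig(
                    family=family, balancing=balancing, n_search=n_search, seeds=seeds
                )
                model = tune_and_fit(train, feature_cols, label_col, cfg, seed, mode)
                aucs.append(auprc(y_test, model.predict_proba(test)))
            aucs = np.asarray(aucs)
            t_stat, p = welch_test(aucs, baselines)
            rows.append(
                {
                    "message_id": message_id, "mode": mode,
                    "family": family, "balancing": balancing,
                    "auprc_mean": float(np.nanmean(aucs)),
                    "auprc_sd": float(np.nanstd(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                    "baseline_mean": float(np.nanmean(baselines)),
                    "baseline_sd": float(np.nanstd(baselines, ddof=1)),
                    "welch_t": t_stat, "welch_p": p,
                }
            )
    report = pd.DataFrame(rows)
    best = report.loc[report["auprc_mean"].idxmax()]
    return MessageEvaluation(
        message_id=message_id,
        mode=mode,
        rows=report,
        best_family=str(best["family"]),
        best_balancing=str(best["balancing"]),
        baseline_auprcs=baselines,
    )
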