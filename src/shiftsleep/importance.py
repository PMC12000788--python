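"""Model explanation: permutation importance and Shapley attributions.

Shapley values are estimated with a permutation-sampling estimator in
probability space against a fixed background row (training feature means).
For every sampled feature ordering the marginal contributions telescope to
``f(x) - f(background)``, so per-sample additivity (base value plus the sum
of contributions equals the predicted probability) holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import auprc

logger = logging.getLogger(__name__)


def permutation_importance(
    model,
    test: pd.DataFrame,
    label_col: str,
    feature: str,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """AUPRC decrease after permuting one feature column, per repeat."""
    y = test[label_col].to_numpy(dtype=int)
    base = auprc(y, model.predict_proba(test))
    rng = np.random.default_rng(seed)
    out = np.empty(n_repeats)
    shuffled = test.copy()
    for rep in range(n_repeats):
        shuffled[feature] = rng.permutation(test[feature].to_numpy())
        out[rep] = base - auprc(y, model.predict_proba(shuffled))
    return out


def permutation_importance_all(
    model,
    test: pd.DataFrame,
    label_col: str,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean/SD AUPRC decrease for every model feature.

    Permutations derive from the run seed offset by feature index, so each
    feature's repeats are reproducible independently.
    """
    rows = []
    for j, feature in enumerate(model.feature_names):
        decreases = permutation_importance(
            model, test, label_col, feature, n_repeats, seed + j
        )
        rows.append(
            {
                "feature": feature,
                "auprc_decrease_mean": float(decreases.mean()),
                "auprc_decrease_sd": float(decreases.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def shapley_attribution(
    model,
    test: pd.DataFrame,
    background: np.ndarray | None = None,
    n_permutations: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-sample per-feature Shapley contributions in probability space.

    Returns ``(contributions, base_value)`` where ``contributions`` has shape
    (n_samples, n_features) and ``base_value + contributions.sum(axis=1)``
    equals the model's predicted probability for every sample.

    ``background`` is the reference feature vector (defaults to the test-set
    column means).  Antithetic permutation pairs halve the estimator noise.
    """
    feats = model.feature_names
    X = test[feats].to_numpy(dtype=float)
    n, f = X.shape
    if background is None:
        background = X.mean(axis=0)
    background = np.asarray(background, dtype=float).reshape(1, f)

    est = model.estimator
    pos = list(est.classes_).index(1)
    base_value = float(est.predict_proba(background)[0, pos])

    rng = np.random.default_rng(seed)
    perms = []
    for _ in range(max(1, n_permutations // 2)):
        p = rng.permutation(f)
        perms.append(p)
        perms.append(p[::-1])
    perms = perms[:n_permutations] if n_permutations > 1 else perms[:1]

    contrib = np.zeros((n, f))
    for p in perms:
        # rows[k] = background with features p[:k] taken from x
        for i in range(n):
            grid = np.repeat(background, f + 1, axis=0)
            for k in range(1, f + 1):
                grid[k:, p[k - 1]] = X[i, p[k - 1]]
            preds = est.predict_proba(grid)[:, pos]
            contrib[i, p] += np.diff(preds)
    contrib /= len(perms)
    return contrib, base_value


def global_shap(contributions: np.ndarray, feature_names: list[str]) -> pd.Series:
    """Global importance: mean absolute contribution per feature."""
    return pd.Series(
        np.abs(contributions).mean(axis=0), index=feature_names, name="mean_abs_shap"
    )


@dataclass
class ImportanceReport:
    """Joint top-5 importance table for one (message, mode, configuration)."""

    message_id: int
    mode: str
    family: str
    balancing: str
    table: pd.DataFrame  # per feature: perm mean/SD, shap mean/SD, reported flag


def aggregate_and_rank(
    perm_runs: list[pd.DataFrame],
    shap_runs: list[pd.Series],
    top_k: int = 5,
    floor: float = 0.01,
) -> pd.DataFrame:
    """Average per-run importances and flag the jointly-top-``top_k`` features.

    A feature is ``reported`` only when it ranks in the top ``top_k`` by both
    the mean AUPRC decrease and the mean absolute Shapley value, with both
    means at least ``floor``.
    """
    if not perm_runs or not shap_runs:
        raise ValueError("need at least one run of each importance measure")
    perm = pd.concat(perm_runs, axis=0).groupby(level=0)
    perm_mean = perm["auprc_decrease_mean"].mean()
    perm_sd = perm["auprc_decrease_mean"].std(ddof=1) if len(perm_runs) > 1 else (
        perm_runs[0]["auprc_decrease_sd"]
    )
    shap_mat = pd.concat(shap_runs, axis=1)
    shap_mean = shap_mat.mean(axis=1)
    shap_sd = shap_mat.std(axis=1, ddof=1) if len(shap_runs) > 1 else (
        pd.Series(0.0, index=shap_mean.index)
    )

    table = pd.DataFrame(
        {
            "auprc_decrease_mean": perm_mean,
            "auprc_decrease_sd": perm_sd,
            "shap_mean": shap_mean,
            "shap_sd": shap_sd,
        }
    )
    top_perm = set(table["auprc_decrease_mean"].nlargest(top_k).index)
    top_shap = set(table["shap_mean"].nlargest(top_k).index)
    table["reported"] = [
        (f in top_perm and f in top_shap
         and table.at[f, "auprc_decrease_mean"] >= floor
         and table.at[f, "shap_mean"] >= floor)
        for f in table.index
    ]
    return table.sort_values("auprc_decrease_mean", ascending=False)
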