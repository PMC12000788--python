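"""Agglomerative characterization of participant-days.

Ward linkage on standardized daily features (well-being and sleep-quality
metrics withheld), dendrogram cuts at 0.7 x the maximum merge height and at
a fixed secondary threshold, PCA-to-95%-variance + t-SNE embedding, and
per-cluster profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .features import CLUSTER_FEATURES

logger = logging.getLogger(__name__)


def select_cluster_features(
    daily: pd.DataFrame, feature_cols: list[str] | None = None
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Standardized feature matrix for clustering.

    Uses the always-available daily features (well-being, sleep quality, and
    event-conditional optional features withheld), drops rows with any
    missing retained feature, drops zero-variance columns with a warning,
    and z-scores each column across all participants.

    Returns ``(matrix, kept_feature_names, kept_rows)`` where ``kept_rows``
    is the participant/date frame aligned with the matrix rows.
    """
    cols = list(feature_cols) if feature_cols is not None else list(CLUSTER_FEATURES)
    sub = daily[["participant", "date"] + cols].dropna(subset=cols)
    X = sub[cols].to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        logger.warning("dropping zero-variance features: %s", dropped)
        cols = [c for c, k in zip(cols, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    X = (X - X.mean(axis=0)) / sd
    return X, cols, sub[["participant", "date"]].reset_index(drop=True)


@dataclass
class ClusterModel:
    """Ward merge tree with primary/secondary cuts over standardized days."""

    X: np.ndarray
    feature_names: list[str]
    index: pd.DataFrame  # participant, date per row
    Z: np.ndarray  # scipy linkage matrix
    primary_threshold: float
    secondary_threshold: float
    labels_primary: np.ndarray = field(init=False)
    labels_secondary: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels_primary = cut(self.Z, self.primary_threshold)
        self.labels_secondary = cut(self.Z, self.secondary_threshold)

    @property
    def max_merge_height(self) -> float:
        return float(self.Z[-1, 2])


def ward_cluster(
    X: np.ndarray,
    feature_names: list[str] | None = None,
    index: pd.DataFrame | None = None,
    primary_threshold: float | None = None,
    secondary_threshold: float = 31.0,
) -> ClusterModel:
    """Ward-linkage agglomeration (Euclidean on standardized features).

    The primary cut defaults to 0.7 x the maximum merge height; both cuts
    are stored and deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Z = linkage(X, method="ward")
    if primary_threshold is None:
        primary_threshold = 0.7 * float(Z[-1, 2])
    if primary_threshold <= 0 or secondary_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    if index is None:
        index = pd.DataFrame({"row": np.arange(X.shape[0])})
    return ClusterModel(X, feature_names, index, Z, primary_threshold, secondary_threshold)


def cut(Z: np.ndarray, threshold: float) -> np.ndarray:
    """Flat cluster labels from cutting the merge tree at a height."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return fcluster(Z, t=threshold, criterion="distance")


def embed(
    X: np.ndarray,
    seed: int = 0,
    variance: float = 0.95,
    perplexity: float = 30.0,
) -> np.ndarray:
    """2-D t-SNE of the principal components explaining >= ``variance``.

    PCA retains the smallest component count whose cumulative explained
    variance reaches the target; coordinates are reproducible under a fixed
    seed.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= perplexity:
        raise ValueError(
            f"n={n} too small for perplexity {perplexity}; lower the perplexity"
        )
    pca = PCA(n_components=min(n, X.shape[1]), random_state=seed)
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance) + 1)
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
        learning_rate="auto",
    )
    return tsne.fit_transform(scores[:, :k])


def n_components_for_variance(X: np.ndarray, variance: float = 0.95) -> int:
    """Smallest PCA component count reaching the cumulative-variance target."""
    pca = PCA(n_components=min(X.shape), random_state=0)
    pca.fit(np.asarray(X, dtype=float))
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, variance) + 1)


def profile(
    model: ClusterModel,
    daily: pd.DataFrame,
    level: str = "primary",
) -> pd.DataFrame:
    """Per-cluster feature means, including the withheld well-being metrics.

    Adds narrative flags for the extreme clusters (lowest mean sleep
    duration, highest mean steps).
    """
    labels = model.labels_primary if level == "primary" else model.labels_secondary
    merged = model.index.copy()
    merged["cluster"] = labels
    merged = merged.merge(daily, on=["participant", "date"], how="left")
    numeric = [
        c for c in merged.columns
        if c not in ("participant", "date", "cluster")
        and pd.api.types.is_numeric_dtype(merged[c])
    ]
    prof = merged.groupby("cluster")[numeric].mean()
    prof["n_days"] = merged.groupby("cluster").size()
    prof["flag_shortest_sleep"] = False
    prof["flag_most_steps"] = False
    if "sleep_duration" in prof:
        prof.loc[prof["sleep_duration"].idxmin(), "flag_shortest_sleep"] = True
    if "steps" in prof:
        prof.loc[prof["steps"].idxmax(), "flag_most_steps"] = True
    return prof
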