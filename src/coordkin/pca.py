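"""Outlier-downweighted PCA variable selection.

The feature table (one row per sequence, one column per descriptive
variable) is z-scored; observations whose Euclidean distance to the
centroid of the z-scored cloud exceeds the mean distance by more than
4 SDs of the distance distribution are downweighted to 0.5; a weighted
PCA is computed; and the variables whose per-component loadings,
normalized by the component's maximum absolute loading, exceed 0.75 on
any of the examined leading components are selected and grouped into
functional clusters by their a-priori category tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

OUTLIER_SD_MULTIPLIER = 4.0
OUTLIER_WEIGHT = 0.5
LOADING_THRESHOLD = 0.75


@dataclass
class PcaResult:
    scores: np.ndarray                  # observations x components
    loadings: np.ndarray                # variables x components (unit eigenvectors)
    explained_variance_pct: np.ndarray  # per component, sums to 100
    weights: np.ndarray                 # per observation, in {1.0, 0.5}
    variable_names: tuple[str, ...]
    selected_variables: dict[str, list[int]] = field(default_factory=dict)
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def normalized_loadings(self, pc: int) -> np.ndarray:
        """Loadings of one component scaled by its maximum absolute loading."""
        col = self.loadings[:, pc]
        m = np.max(np.abs(col))
        if m == 0:
            return col
        return col / m


def zscore_matrix(
    X: pd.DataFrame | np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, list[str], list[str]]:
    """Columnwise z-scoring; constant columns are dropped and reported.

    Returns (Z, kept column names, dropped column names).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
        names = [f"v{i}" for i in range(A.shape[1])]
    sd = A.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant")
    Z = (A[:, keep] - A[:, keep].mean(axis=0)) / sd[keep]
    kept = [n for n, k in zip(names, keep) if k]
    dropped = [n for n, k in zip(names, keep) if not k]
    return Z, kept, dropped


def detect_outliers(
    Z: np.ndarray,
    k: float = OUTLIER_SD_MULTIPLIER,
    w: float = OUTLIER_WEIGHT,
) -> np.ndarray:
    """Per-observation PCA weights from the centroid-distance rule.

    An observation gets weight ``w`` (default 0.5) iff its Euclidean
    distance to the column-mean centroid exceeds the mean distance by more
    than ``k`` (default 4) standard deviations of the distances; weight
    1.0 otherwise.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    d = np.linalg.norm(Z - Z.mean(axis=0), axis=1)
    if np.isinf(k):
        return np.ones(Z.shape[0])
    cut = d.mean() + k * d.std(ddof=1)
    return np.where(d > cut, w, 1.0)


def weighted_pca(
    Z: np.ndarray,
    weights: np.ndarray | None = None,
    variable_names: tuple[str, ...] | None = None,
) -> PcaResult:
    """Eigendecomposition of the weighted covariance of the z-scored data.

    C = sum_i w_i (z_i - mu_w)(z_i - mu_w)^T / sum_i w_i with the weighted
    mean mu_w. Components are ordered by decreasing eigenvalue with a
    deterministic sign convention (each component's largest-magnitude
    loading is positive). Numerically rank-deficient directions
    (eigenvalue below 1e-12 of the total) are dropped.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    mu = (weights[:, None] * Z).sum(axis=0) / weights.sum()
    Zc = Z - mu
    C = (weights[:, None] * Zc).T @ Zc / weights.sum()
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = max(float(evals.sum()), 1e-300)
    keep = evals > 1e-12 * total
    evals, evecs = evals[keep], evecs[:, keep]
    # deterministic sign: largest-|loading| entry positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Zc @ evecs
    pct = 100.0 * evals / evals.sum()  # over retained (full-rank) components
    names = variable_names or tuple(f"v{i}" for i in range(p))
    return PcaResult(
        scores=scores,
        loadings=evecs,
        explained_variance_pct=pct,
        weights=weights,
        variable_names=tuple(names),
    )


def select_variables(
    result: PcaResult,
    threshold: float = LOADING_THRESHOLD,
    n_pcs: int = 1,
) -> dict[str, list[int]]:
    """Variables whose normalized loading exceeds the threshold.

    Each examined component's loadings are scaled by that component's
    maximum absolute loading; a variable is selected when its scaled
    absolute loading is strictly above ``threshold`` on any of the first
    ``n_pcs`` components. Returns {variable: [components that selected it]}
    and stores the set (plus the tag-based clusters) on the result.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    selected: dict[str, list[int]] = {}
    for pc in range(min(n_pcs, result.loadings.shape[1])):
        norm = np.abs(result.normalized_loadings(pc))
        for i, name in enumerate(result.variable_names):
            if norm[i] > threshold:
                selected.setdefault(name, []).append(pc)
    result.selected_variables = selected
    return selected


def cluster_selected(
    result: PcaResult, categories: dict[str, str]
) -> dict[str, list[str]]:
    """Partition the selected variables into functional clusters by tag.

    The grouping is metadata-driven: every variable carries an a-priori
    category (torso movements, head movements, head-torso coordination,
    steering error) and clusters are simply the selected set split by tag.
    """
    clusters: dict[str, list[str]] = {}
    for name in result.selected_variables:
        tag = categories.get(name, "other")
        clusters.setdefault(tag, []).append(name)
    result.clusters = clusters
    return clusters


def separation_test(
    scores: np.ndarray, groups: np.ndarray, pc: int = 0
) -> tuple[float, float]:
    """Two-sample t-test on one component's scores between two groups."""
    scores = np.asarray(scores)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("groups must have exactly two levels")
    a = scores[groups == levels[0], pc]
    b = scores[groups == levels[1], pc]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = _stats.ttest_ind(a, b)
    return float(t), float(p)
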