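"""Cross-cell analyses of post-spike-filter phenotypes.

Given a population table (one row per cell: normalized PSF curve, smooth
basis coefficients, timing features, spatial coherence, group label), this
module provides

- PCA of the PSF curves and of the 10 smooth coefficients ("factor space");
- k-means (k = 2) clustering of unit-power PSFs under correlation distance,
  with clusters labelled bursty / refractory by their mean burstiness;
- per-timepoint Spearman correlation of the PSF (or smoothed ACG) with
  spatial coherence;
- multivariable regression of coherence on timing features or factor scores,
  with optional two-way interactions, reporting predicted-vs-observed
  Spearman and Pearson r^2;
- pooled-SD Cohen's d effect sizes and place-cell fractions per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClusterResult",
    "RegressionResult",
    "PCAResult",
    "pca_psfs",
    "cluster_psfs",
    "timepoint_coherence_correlation",
    "regress_coherence",
    "cohens_d",
    "place_cell_fraction",
]


@dataclass(frozen=True)
class PCAResult:
    components: np.ndarray  # (n_components, n_dims)
    scores: np.ndarray  # (n_cells, n_components)
    variance_explained: np.ndarray  # fractions summing to 1


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # array of "bursty" / "refractory" strings
    assignments: np.ndarray  # raw 0/1 cluster indices
    centroids: np.ndarray  # (2, n_dims) mean curves per cluster
    within_correlation: float  # mean pairwise r within clusters
    between_correlation: float  # mean pairwise r across clusters


@dataclass(frozen=True)
class RegressionResult:
    coefficients: pd.Series
    predicted: np.ndarray
    observed: np.ndarray
    spearman_r2: float
    pearson_r2: float
    ridge_used: float | None = None


def pca_psfs(curves: np.ndarray, n_components: int | None = None) -> PCAResult:
    """PCA of PSF curves (or of smooth coefficients, "factor space").

    Rows are cells.  With 10-dimensional coefficient input the full set of
    10 components explains all the variance; ``variance_explained`` holds
    the per-component fractions of total variance (summing to 1 when all
    components are kept).
    """
    X = np.asarray(curves, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2D array with at least 2 cells")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("PCA undefined for constant input")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        components=pca.components_,
        scores=scores,
        variance_explained=pca.explained_variance_ratio_,
    )


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center and unit-normalize each row, so Euclidean distance between
    standardized rows is a monotone function of correlation distance:
    ||z_a - z_b||^2 = 2 n (1 - r(a, b)) after this transform."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant PSF row: correlation distance undefined")
    return Xc / norms


def cluster_psfs(
    fnorm_curves: np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_init: int = 50,
    burstiness_values: np.ndarray | None = None,
) -> ClusterResult:
    """k-means (k = 2) on unit-power PSFs under correlation distance.

    Curves are row-standardized so Euclidean k-means optimizes the
    correlation-distance objective exactly.  The cluster with the larger
    mean burstiness (integral over 0-30 ms, computed from the curves if not
    supplied) is labelled "bursty", the other "refractory".
    """
    X = np.asarray(fnorm_curves, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least {k} cells to form {k} clusters")
    Z = _standardize_rows(X)
    if np.allclose(Z - Z[0], 0):
        raise ValueError("all PSFs identical: clustering degenerate")

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assign = km.fit_predict(Z)
    if len(np.unique(assign)) < k:
        raise ValueError("degenerate clustering: empty cluster")

    if burstiness_values is None:
        # integral of the curve over the first 30 ms (1-ms grid assumed)
        n30 = min(31, X.shape[1])
        burstiness_values = np.trapezoid(
            X[:, :n30], np.arange(n30) * 1e-3, axis=1
        )
    burst_mean = [burstiness_values[assign == c].mean() for c in range(k)]
    bursty_cluster = int(np.argmax(burst_mean))
    labels = np.where(assign == bursty_cluster, "bursty", "refractory")

    centroids = np.vstack([X[assign == c].mean(axis=0) for c in range(k)])
    R = np.corrcoef(X)
    same = assign[:, None] == assign[None, :]
    off_diag = ~np.eye(len(assign), dtype=bool)
    within = float(R[same & off_diag].mean())
    between = float(R[~same].mean()) if np.any(~same) else np.nan
    return ClusterResult(
        labels=labels,
        assignments=assign,
        centroids=centroids,
        within_correlation=within,
        between_correlation=between,
    )


def timepoint_coherence_correlation(
    curves: np.ndarray,
    coherence: np.ndarray,
    method: str = "spearman",
) -> np.ndarray:
    """Correlation between each curve timepoint and spatial coherence.

    ``curves`` holds one PSF (or 10-ms-smoothed ACG) per row on the 1-ms
    lag grid; returns the per-lag correlation across cells.
    """
    X = np.asarray(curves, dtype=float)
    y = np.asarray(coherence, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("one coherence value per cell required")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    if np.all(y == y[0]):
        raise ValueError("constant coherence: correlation undefined")
    if method == "spearman":
        # rank once, then Pearson of ranks column-wise (vectorized Spearman)
        yr = stats.rankdata(y)
        Xr = np.apply_along_axis(stats.rankdata, 0, X)
        return _columnwise_pearson(Xr, yr)
    if method == "pearson":
        return _columnwise_pearson(X, y)
    raise ValueError(f"unknown method {method!r}")


def _columnwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = Xc.T @ yc
    den = np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


def _interaction_design(F: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    names = list(F.columns)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            cols[f"{a}:{b}"] = F[a].to_numpy() * F[b].to_numpy()
    return pd.concat([F, pd.DataFrame(cols, index=F.index)], axis=1)


def regress_coherence(
    features: pd.DataFrame,
    coherence: np.ndarray,
    interactions: bool = True,
    ridge: float | None = None,
) -> RegressionResult:
    """Least-squares regression of coherence on timing features.

    ``features`` may hold the seven PSF features or PCA factor scores;
    with ``interactions=True`` all pairwise products are added to the main
    effects.  Predictors are z-scored before fitting.  A rank-deficient
    design falls back to a small ridge with a warning.  Reports the
    Spearman and Pearson r^2 between predicted and observed coherence.
    """
    y = np.asarray(coherence, dtype=float)
    F = features.copy()
    if interactions:
        F = _interaction_design(F)
    # standardize predictors; drop constant columns
    sd = F.std(axis=0, ddof=0)
    keep = sd > 0
    F = (F.loc[:, keep] - F.loc[:, keep].mean(axis=0)) / sd[keep]
    X = np.column_stack([np.ones(len(F)), F.to_numpy()])
    names = ["intercept"] + list(F.columns)

    ridge_used = ridge
    if ridge is None:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1] or X.shape[0] <= X.shape[1]:
            ridge_used = 1e-6
            warnings.warn(
                "rank-deficient regression design; ridge-stabilized",
                RuntimeWarning,
                stacklevel=2,
            )
    if ridge_used:
        P = ridge_used * np.eye(X.shape[1])
        P[0, 0] = 0.0
        coefs = np.linalg.solve(X.T @ X + P, X.T @ y)
    else:
        coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coefs

    sp = stats.spearmanr(pred, y).statistic
    pe = stats.pearsonr(pred, y).statistic
    return RegressionResult(
        coefficients=pd.Series(coefs, index=names),
        predicted=pred,
        observed=y,
        spearman_r2=float(sp**2),
        pearson_r2=float(pe**2),
        ridge_used=ridge_used,
    )


def cohens_d(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Cohen's d: (mean_a - mean_b) / pooled standard deviation."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def place_cell_fraction(
    coherence: np.ndarray,
    groups: np.ndarray | None = None,
    threshold: float = 0.3,
) -> dict[str, float]:
    """Fraction of cells at/above the place-cell coherence threshold.

    With ``groups`` given, returns one fraction per group; an empty group
    maps to NaN.
    """
    c = np.asarray(coherence, dtype=float)
    if groups is None:
        return {"all": float(np.mean(c >= threshold))}
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        out[str(g)] = float(np.mean(c[sel] >= threshold)) if sel.any() else np.nan
    return out
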