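"""Descriptive and multivariate statistics over the trait panel.

Covers the coefficient of variation and (adjusted Fisher-Pearson)
skewness per trait, pairwise Pearson correlations on pairwise-complete
cases with t-distribution p-values, PCA of the standardized trait matrix
(eigen-decomposition of the correlation matrix) and hierarchical
clustering of traits in the retained PC space (Ward linkage), which
groups traits into co-varying blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class TraitMatrix:
    """Accessions x traits, numeric, missing allowed."""

    data: pd.DataFrame
    provenance: str = "mixed-model prediction"  # or "raw mean"

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise InputError("trait columns must be uniquely named")
        if len(self.data) < 3 or self.data.shape[1] < 2:
            raise InputError("need >= 3 accessions and >= 2 traits")


@dataclass
class DescriptiveStats:
    mean: float
    sd: float
    cv_percent: float  # NaN with flag when the mean is 0
    skewness: float
    cv_undefined: bool
    n: int


def descriptive_stats(values) -> DescriptiveStats:
    """Mean, SD, CV% and adjusted Fisher-Pearson skewness.

    CV = 100 * SD / mean (undefined at mean 0, flagged).  Skewness uses
    the sample-size-corrected estimator
    G1 = sqrt(n(n-1)) / (n-2) * m3 / m2^(3/2).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        raise InputError(f"need n >= 3 observations, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv_undefined = mean == 0
    cv = np.nan if cv_undefined else 100.0 * sd / mean
    skew = float(stats.skew(x, bias=False))
    return DescriptiveStats(mean, sd, cv, skew, cv_undefined, n)


def correlation_matrix(tm: TraitMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p per trait pair on pairwise-complete cases.

    Matrices are symmetric with unit diagonal (p = 0 on the diagonal).
    Pairs involving a constant column, or with fewer than 3 complete
    cases, are NaN-flagged.
    """
    cols = list(tm.data.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = tm.data[[cols[i], cols[j]]].dropna()
            if len(sub) < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0:
                logger.warning("constant column in pair (%s, %s); r undefined",
                               cols[i], cols[j])
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rv, pv = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rv
            p[i, j] = p[j, i] = pv
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # accessions x PCs
    loadings: pd.DataFrame  # traits x PCs
    percent_variance: np.ndarray  # sums to 100


def pca_traits(tm: TraitMatrix, standardize: bool = True) -> PCAResult:
    """PCA of the trait matrix on complete cases.

    With ``standardize`` this is the eigen-decomposition of the trait
    correlation matrix; percent variance per PC sums to 100.  Component
    signs are fixed so each PC's largest-magnitude loading is positive.
    """
    complete = tm.data.dropna()
    if len(complete) < len(tm.data):
        logger.warning("pca_traits: %d incomplete accessions dropped",
                       len(tm.data) - len(complete))
    if len(complete) < 3:
        raise InputError("fewer than 3 complete cases for PCA")
    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(Vt.shape[0]):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eig = S**2 / (len(complete) - 1)
    pct = 100.0 * eig / eig.sum()
    pcs = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=complete.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=tm.data.columns, columns=pcs),
        percent_variance=pct,
    )


def cluster_traits(
    pca: PCAResult, k: int = 3, n_pcs: int | None = None, method: str = "ward"
) -> dict[str, int]:
    """Group traits into ``k`` clusters in the retained PC space.

    Trait coordinates are the loadings scaled by the PC standard
    deviations (so distances respect explained variance); agglomerative
    clustering with Ward linkage, cut at k.  k-means is available via
    ``method='kmeans'``.
    """
    n_traits = len(pca.loadings)
    if k < 2 or k > n_traits:
        raise InputError(f"k must be in [2, {n_traits}], got {k}")
    if n_pcs is None:
        n_pcs = min(n_traits, pca.scores.shape[1])
    sdev = np.sqrt(pca.percent_variance[:n_pcs])
    coords = pca.loadings.iloc[:, :n_pcs].to_numpy() * sdev
    if method == "ward":
        Z = linkage(coords, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif method == "kmeans":
        from scipy.cluster.vq import kmeans2

        _, labels = kmeans2(coords, k, seed=0, minit="++")
        labels = labels + 1
    else:
        raise InputError(f"unknown clustering method {method!r}")
    return dict(zip(pca.loadings.index, (int(l) for l in labels)))
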