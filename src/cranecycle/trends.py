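"""Environmental-series standardization and correlation-matrix PCA.

Heterogeneous long-term series (surface water %, temperature, precipitation,
human density) are put on comparable scales before trend interpretation:
water as a percentage of the site's historical maximum, climate variables
as absolute anomalies from the long-term mean, and human density as a
proportional change relative to a reference year.  The seasonal covariate
set used in survival models is reduced by PCA on the correlation matrix
(the variables mix °C, mm, %, persons/km², so covariance PCA would be
dominated by units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from sklearn.base import BaseEstimator


def _as_array(series):
    return np.asarray(series, dtype=float)


def standardize_water(series):
    """Express a water-surface series as % of the site's maximum (max → 100)."""
    v = _as_array(series)
    m = np.nanmax(v)
    if not m > 0:
        raise ValueError("water series has no positive value; cannot standardize")
    out = 100.0 * v / m
    return pd.Series(out, index=series.index) if isinstance(series, pd.Series) else out


def anomalies(series):
    """Absolute anomalies from the long-term mean (output mean is 0)."""
    v = _as_array(series)
    if len(v) < 2:
        raise ValueError("anomalies need at least 2 values")
    out = v - np.nanmean(v)
    return pd.Series(out, index=series.index) if isinstance(series, pd.Series) else out


def proportional_change(series: pd.Series, ref_year: int = 2000):
    """Series relative to its value in ``ref_year`` (which maps to exactly 1).

    ``series`` must be indexed by year and contain a non-zero reference value.
    """
    if ref_year not in series.index:
        raise ValueError(f"reference year {ref_year} not in series")
    ref = float(series.loc[ref_year])
    if ref == 0:
        raise ValueError("reference value is zero; proportional change undefined")
    return series / ref


def linear_trend(series):
    """Least-squares slope and intercept of value on year (or on 0..n-1)."""
    v = _as_array(series)
    x = np.asarray(series.index, float) if isinstance(series, pd.Series) \
        else np.arange(len(v), dtype=float)
    slope, intercept = np.polyfit(x, v, 1)
    return float(slope), float(intercept)


@dataclass
class PCASummary:
    """Loadings, explained-variance fractions and per-year scores."""
    loadings: pd.DataFrame            # variables × components
    explained_variance_ratio: np.ndarray
    cumulative_variance: np.ndarray
    scores: pd.DataFrame              # years × components
    n_nontrivial: int


class CorrelationPCA(BaseEstimator):
    """PCA of the correlation matrix (columns standardized internally).

    Components are ordered by decreasing variance; each loading vector is
    oriented so its largest-magnitude element is positive (the eigenvector
    sign is otherwise arbitrary).  With n rows and q variables at most
    min(n-1, q) components carry variance; trailing components are exactly
    zero-variance and the reported fractions sum to 1.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : DataFrame (variables × PC1..PCm)
    explained_variance_ratio_, cumulative_variance_ : ndarray
    n_nontrivial_ : number of components with non-negligible variance
    mean_, scale_ : per-column standardization constants (sd uses n-1)
    """

    def __init__(self, eps: float = 1e-10):
        self.eps = eps

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("PCA needs at least 2 rows")
        self.mean_ = X.mean()
        self.scale_ = X.std(ddof=1)
        bad = self.scale_[~(self.scale_ > 0)].index.tolist()
        if bad:
            raise ValueError(f"constant column(s) cannot enter correlation PCA: {bad}")
        Z = ((X - self.mean_) / self.scale_).to_numpy(dtype=float)
        n = Z.shape[0]
        # eigen-decomposition of the correlation matrix via SVD of Z/sqrt(n-1)
        U, s, Vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
        eig = s ** 2
        # orient: largest-|loading| element of each component positive
        V = Vt.T
        flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
        flip[flip == 0] = 1.0
        V = V * flip
        comp_names = [f"PC{i + 1}" for i in range(V.shape[1])]
        self.components_ = V
        self.loadings_ = pd.DataFrame(V, index=X.columns, columns=comp_names)
        total = eig.sum()
        self.explained_variance_ = eig
        self.explained_variance_ratio_ = eig / total
        self.cumulative_variance_ = np.cumsum(self.explained_variance_ratio_)
        self.n_nontrivial_ = int(np.sum(eig > self.eps * eig[0]))
        self.columns_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[self.columns_]
        Z = (X - self.mean_) / self.scale_
        scores = Z.to_numpy(float) @ self.components_
        return pd.DataFrame(scores, index=X.index, columns=self.loadings_.columns)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def pca_reduce(matrix: pd.DataFrame) -> PCASummary:
    """Correlation-matrix PCA of a years × variables table."""
    est = CorrelationPCA().fit(matrix)
    scores = est.transform(matrix)
    return PCASummary(
        loadings=est.loadings_,
        explained_variance_ratio=est.explained_variance_ratio_,
        cumulative_variance=est.cumulative_variance_,
        scores=scores,
        n_nontrivial=est.n_nontrivial_,
    )
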