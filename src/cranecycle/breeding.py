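"""Binomial/Gaussian GLMs with all-subsets AIC model averaging.

The workflow mirrors standard multimodel inference for breeding-performance
data: scale the predictors, screen collinearity (VIF > 3 dropped, pairwise
|r| checked against 0.7), fit every subset of the predictors by GLM with the
intercept always included, weight models by exp(-ΔAIC/2), and report
full-average coefficients with unconditional standard errors and Akaike
importance sums.  The same engine serves phenology responses with a
Gaussian family and annual-survival-versus-principal-component models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

try:  # moved between statsmodels versions
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError, PerfectSeparationWarning)
except ImportError:  # pragma: no cover
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
    PerfectSeparationWarning = UserWarning


def scale_predictors(X: pd.DataFrame):
    """Centre and scale each column to mean 0, sd 1 (divisor n-1).

    Returns ``(X_scaled, means, sds)``.  A constant column cannot be scaled
    and raises ``ValueError`` naming it.
    """
    means = X.mean()
    sds = X.std(ddof=1)
    bad = sds[~(sds > 0)].index.tolist()
    if bad:
        raise ValueError(f"cannot scale constant column(s): {bad}")
    return (X - means) / sds, means, sds


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF_j = 1/(1-R²) of column j regressed (with intercept) on the rest."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_screen(X: pd.DataFrame, threshold: float = 3.0):
    """Iteratively drop the highest-VIF column while any VIF exceeds ``threshold``.

    Perfectly collinear columns have R² = 1 and are treated as infinite VIF
    (dropped first).  Returns ``(retained_columns, report)`` where the report
    lists each round's VIFs and the column dropped.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 columns")
    cols = list(X.columns)
    report = []
    while len(cols) >= 2:
        M = X[cols].to_numpy(dtype=float)
        vifs = {c: _vif_one(M, j) for j, c in enumerate(cols)}
        worst = max(vifs, key=lambda c: vifs[c])
        dropped = vifs[worst] > threshold
        report.append({"vifs": dict(vifs), "dropped": worst if dropped else None})
        if not dropped:
            break
        cols.remove(worst)
    return cols, report


def corr_check(X: pd.DataFrame, cutoff: float = 0.7):
    """Largest absolute pairwise Pearson correlation and whether it passes.

    Returns ``(max_abs_r, ok)`` with ``ok = max_abs_r < cutoff``.
    """
    r = X.corr().to_numpy()
    iu = np.triu_indices_from(r, k=1)
    max_abs = float(np.max(np.abs(r[iu]))) if len(iu[0]) else 0.0
    return max_abs, max_abs < cutoff


@dataclass
class GLMFit:
    """One fitted GLM: terms include the leading intercept."""
    terms: list
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    aic: float
    n: int
    k: int
    converged: bool
    separation: bool = False

    def __post_init__(self):
        # AIC identity is part of the contract
        assert np.isclose(self.aic, -2.0 * self.loglik + 2.0 * self.k)


_FAMILIES = {
    "binomial": sm.families.Binomial,
    "gaussian": sm.families.Gaussian,
}


def fit_binomial_glm(y, X, family: str = "binomial") -> GLMFit:
    """Fit a GLM of ``y`` on ``X`` plus an intercept.

    ``family="binomial"`` uses a logit link and requires binary y;
    ``family="gaussian"`` is an identity-link least-squares fit (used for
    day-of-year and duration responses).  Fitting is IRLS with tolerance
    1e-8 and at most 100 iterations.  Complete separation is flagged
    (``separation=True``, ``converged=False``) but the fit is retained.

    AIC is ``-2 loglik + 2 k`` with k the number of estimated coefficients.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y, dtype=float)
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial family requires 0/1 responses")
    X = pd.DataFrame(X)
    terms = ["(Intercept)"] + list(X.columns)
    A = np.column_stack([np.ones(len(y))] + [X[c].to_numpy(float) for c in X.columns])
    sep = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, A, family=_FAMILIES[family]()).fit(maxiter=100, tol=1e-8)
        except PerfectSeparationError:  # pragma: no cover - statsmodels>=0.14 warns
            raise
        sep = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    converged = bool(res.converged) and not sep
    k = A.shape[1]
    if family == "gaussian":
        # profile out sigma^2 at its MLE so loglik is the maximized value
        resid = y - A @ res.params
        n = len(y)
        s2 = float(resid @ resid) / n
        loglik = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
    else:
        loglik = float(res.llf)
    fit = GLMFit(
        terms=terms,
        coef=np.asarray(res.params, float),
        se=np.asarray(res.bse, float),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        n=len(y),
        k=k,
        converged=converged,
        separation=sep,
    )
    return fit


@dataclass
class AveragedEstimates:
    """All-subsets AIC model-averaging result.

    ``coef``/``se`` are full-average estimates (a term contributes 0 where
    absent); ``importance`` is each term's Akaike weight sum; ``models`` has
    one row per fitted subset ordered by AIC; ``top_set`` are the model rows
    with ΔAIC at most the threshold (inclusive).
    """
    terms: list
    coef: pd.Series
    se: pd.Series
    importance: pd.Series
    models: pd.DataFrame
    top_set: pd.DataFrame
    warnings: list = field(default_factory=list)


def all_subsets_average(y, X, family: str = "binomial",
                        delta_aic: float = 2.0, aicc: bool = False) -> AveragedEstimates:
    """Fit all 2^p predictor subsets and model-average the coefficients.

    The intercept is always included.  Akaike weights are
    ``w_i = exp(-Δ_i/2) / Σ_j exp(-Δ_j/2)`` over all fitted subsets.  The
    full-average coefficient of a term is ``Σ w_i β_i`` with ``β_i = 0``
    where the term is absent; its unconditional SE follows Burnham &
    Anderson, ``Σ w_i sqrt(se_i² + (β_i - β̄)²)``.  ``aicc=True`` applies
    the small-sample correction ``AIC + 2k(k+1)/(n-k-1)``.
    """
    X = pd.DataFrame(X)
    p = X.shape[1]
    if p > 15:
        raise ValueError("all-subsets averaging is capped at 15 predictors")
    term_names = list(X.columns)
    fits = []
    rows = []
    warns = []
    for r in range(p + 1):
        for subset in itertools.combinations(term_names, r):
            fit = fit_binomial_glm(y, X[list(subset)], family=family)
            crit = fit.aic
            if aicc:
                denom = fit.n - fit.k - 1
                crit = fit.aic + (2.0 * fit.k * (fit.k + 1) / denom if denom > 0 else np.inf)
            if fit.separation:
                warns.append(f"separation in subset {subset or '(intercept-only)'}")
            fits.append(fit)
            rows.append({"terms": subset, "k": fit.k, "loglik": fit.loglik,
                         "aic": crit})
    models = pd.DataFrame(rows)
    models["delta_aic"] = models["aic"] - models["aic"].min()
    w = np.exp(-0.5 * models["delta_aic"].to_numpy())
    models["weight"] = w / w.sum()

    all_terms = ["(Intercept)"] + term_names
    coef = pd.Series(0.0, index=all_terms)
    for fit, wi in zip(fits, models["weight"]):
        for t, b in zip(fit.terms, fit.coef):
            coef[t] += wi * b
    se = pd.Series(0.0, index=all_terms)
    for fit, wi in zip(fits, models["weight"]):
        present = dict(zip(fit.terms, range(len(fit.terms))))
        for t in all_terms:
            if t in present:
                j = present[t]
                se[t] += wi * np.sqrt(fit.se[j] ** 2 + (fit.coef[j] - coef[t]) ** 2)
            else:
                se[t] += wi * abs(0.0 - coef[t])
    importance = pd.Series(
        {t: float(models["weight"][[t in s for s in models["terms"]]].sum())
         for t in term_names})
    importance["(Intercept)"] = 1.0

    order = models.sort_values("aic", kind="mergesort").reset_index(drop=True)
    top = order[order["delta_aic"] <= delta_aic].reset_index(drop=True)
    return AveragedEstimates(terms=all_terms, coef=coef, se=se,
                             importance=importance.reindex(all_terms),
                             models=order, top_set=top, warnings=warns)


class AICModelAverager(BaseEstimator):
    """sklearn-style wrapper around all-subsets AIC model averaging.

    Parameters
    ----------
    family : {"binomial", "gaussian"}, default "binomial"
    delta_aic : float, default 2.0
        Inclusive ΔAIC threshold defining the top model set.
    aicc : bool, default False
        Use the small-sample corrected criterion instead of plain AIC.
    scale : bool, default True
        Standardize predictors (mean 0, sd 1) before fitting, so effect
        sizes are comparable across terms.

    Attributes (after ``fit``)
    --------------------------
    coef_, se_ : pandas Series of full-average estimates per term.
    importance_ : Akaike weight sums per term.
    models_ : per-subset table (terms, k, loglik, aic, delta_aic, weight).
    top_set_ : the ΔAIC ≤ threshold subset of ``models_``.
    """

    def __init__(self, family: str = "binomial", delta_aic: float = 2.0,
                 aicc: bool = False, scale: bool = True):
        self.family = family
        self.delta_aic = delta_aic
        self.aicc = aicc
        self.scale = scale

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if self.scale:
            X, self.scale_means_, self.scale_sds_ = scale_predictors(X)
        result = all_subsets_average(y, X, family=self.family,
                                     delta_aic=self.delta_aic, aicc=self.aicc)
        self.result_ = result
        self.coef_ = result.coef
        self.se_ = result.se
        self.importance_ = result.importance
        self.models_ = result.models
        self.top_set_ = result.top_set
        return self


def recover_effects(nests: pd.DataFrame, true_beta: dict, response: str,
                    covariates: list, family: str = "binomial") -> pd.DataFrame:
    """Validation harness: model-average a simulated table and compare to truth.

    ``true_beta`` maps term name (on the scaled logit scale, plus
    ``"(Intercept)"``) to the generating coefficient.  Reports, per term,
    the averaged estimate, its unconditional SE, and whether the truth lies
    within estimate ± 1.96·SE.
    """
    est = AICModelAverager(family=family).fit(nests[covariates], nests[response])
    rows = []
    for t in est.coef_.index:
        truth = float(true_beta.get(t, 0.0))
        b, s = float(est.coef_[t]), float(est.se_[t])
        rows.append({"term": t, "true": truth, "estimate": b, "se": s,
                     "covered": abs(b - truth) <= 1.96 * s,
                     "sign_match": (b == truth == 0) or np.sign(b) == np.sign(truth)})
    return pd.DataFrame(rows)
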