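"""Core two-sample MR regression estimators, scikit-learn style.

Each estimator consumes per-SNP effect arrays: ``X`` the SNP-exposure betas
(one column per exposure), ``y`` the SNP-outcome betas, and ``se_y`` the
SNP-outcome standard errors (inverse-variance weights are 1/se_y²).  Fitted
attributes carry a trailing underscore; ``get_params``/``set_params`` come
from :class:`sklearn.base.BaseEstimator`, so the estimators compose with
sklearn's ``clone`` and parameter search machinery.

Conventions used throughout: the IVW causal effect is the no-intercept
weighted least-squares slope of y on x; Cochran's Q feeds the multiplicative
random-effects standard error max(1, sqrt(Q/df)); Egger adds a free intercept
(directional-pleiotropy test) with t(J-2) inference after orienting every SNP
to a non-negative exposure beta.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "IVWRegression",
    "EggerRegression",
    "WeightedMedianEstimator",
    "MRPresso",
    "MVMRRegression",
    "weighted_median_point",
]

_Z95 = sps.norm.ppf(0.975)


def _as_1d(a, name, min_len=1):
    a = np.asarray(a, dtype=float).ravel()
    if a.size < min_len:
        raise ValueError(f"{name} needs at least {min_len} SNPs, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _check_se(se):
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    return se


class IVWRegression(BaseEstimator):
    """Inverse-variance-weighted causal-effect estimator.

    No-intercept WLS of SNP-outcome on SNP-exposure betas with weights
    1/se_y².  ``model="fixed"`` uses the analytic fixed-effect SE;
    ``model="multiplicative_random"`` (default) inflates it by
    max(1, sqrt(Q/df)) where Q is Cochran's heterogeneity statistic on
    df = J - 1.  Two-sided normal p-value.
    """

    def __init__(self, model: str = "multiplicative_random"):
        self.model = model

    def fit(self, X, y, se_y):
        if self.model not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown model {self.model!r}")
        bx = _as_1d(X, "X", 2)
        by = _as_1d(y, "y", 2)
        se = _check_se(_as_1d(se_y, "se_y", 2))
        if not (bx.size == by.size == se.size):
            raise ValueError("X, y, se_y must have equal length")
        w = 1.0 / se**2
        sxx = float(w @ bx**2)
        if sxx == 0:
            raise ValueError("all exposure betas are zero")
        beta = float(w @ (bx * by)) / sxx
        se_fixed = float(np.sqrt(1.0 / sxx))
        resid = by - beta * bx
        q = float(w @ resid**2)
        df = bx.size - 1
        self.scale_ = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
        se_hat = se_fixed * (self.scale_ if self.model == "multiplicative_random" else 1.0)
        self.beta_ = beta
        self.coef_ = np.array([beta])
        self.se_ = se_hat
        self.se_fixed_ = se_fixed
        self.ci_low_ = beta - _Z95 * se_hat
        self.ci_high_ = beta + _Z95 * se_hat
        self.pval_ = float(2 * sps.norm.sf(abs(beta / se_hat)))
        self.q_ = q
        self.q_df_ = df
        self.q_pval_ = float(sps.chi2.sf(q, df)) if df > 0 else np.nan
        self.n_snp_ = bx.size
        return self

    def predict(self, X):
        return np.asarray(X, float).ravel() * self.beta_


class EggerRegression(BaseEstimator):
    """MR-Egger: intercept-augmented WLS, the intercept testing pleiotropy.

    SNPs are first oriented so every exposure beta is non-negative (both
    betas of a pair negated where needed).  Slope/intercept SEs use the
    unscaled WLS covariance times max(1, residual standard deviation);
    p-values are two-sided t on J - 2 degrees of freedom.
    """

    def fit(self, X, y, se_y):
        bx = _as_1d(X, "X", 3)
        by = _as_1d(y, "y", 3)
        se = _check_se(_as_1d(se_y, "se_y", 3))
        if not (bx.size == by.size == se.size):
            raise ValueError("X, y, se_y must have equal length")
        flip = bx < 0
        bx = np.where(flip, -bx, bx)
        by = np.where(flip, -by, by)
        if np.ptp(bx) == 0:
            raise ValueError("zero spread in exposure betas after orientation")
        design = sm.add_constant(bx)
        res = sm.WLS(by, design, weights=1.0 / se**2).fit()
        sigma = float(np.sqrt(res.scale))
        base_se = np.sqrt(np.diag(res.normalized_cov_params))
        scaled = base_se * max(1.0, sigma)
        df = bx.size - 2
        self.intercept_ = float(res.params[0])
        self.intercept_se_ = float(scaled[0])
        self.intercept_pval_ = float(2 * sps.t.sf(abs(self.intercept_ / scaled[0]), df))
        self.beta_ = float(res.params[1])
        self.coef_ = np.array([self.beta_])
        self.se_ = float(scaled[1])
        self.pval_ = float(2 * sps.t.sf(abs(self.beta_ / scaled[1]), df))
        tq = sps.t.ppf(0.975, df)
        self.ci_low_ = self.beta_ - tq * self.se_
        self.ci_high_ = self.beta_ + tq * self.se_
        self.scale_ = sigma
        self.df_ = df
        self.n_snp_ = bx.size
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, float).ravel() * self.beta_


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated median of per-SNP ratio estimates.

    Ratios sorted ascending; with normalized weights w the cumulative
    midpoint score is S_j = sum_{i<=j} w_i - w_j/2 and the estimate linearly
    interpolates the sorted ratios at S = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median MR estimator with parametric-bootstrap SE.

    Per-SNP ratios by/bx are weighted by bx²/se_y² (inverse variance of the
    ratio, first order).  Consistent when valid instruments carry >= 50% of
    the weight.  The SE is the standard deviation of the point estimate over
    ``n_boot`` parametric resamples bx* ~ N(bx, se_x), by* ~ N(by, se_y);
    the p-value is two-sided normal.
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, se_y, se_x=None):
        bx = _as_1d(X, "X", 3)
        by = _as_1d(y, "y", 3)
        se = _check_se(_as_1d(se_y, "se_y", 3))
        se_x = (np.zeros_like(bx) if se_x is None
                else _check_se(_as_1d(se_x, "se_x", 3)))
        if np.any(bx == 0):
            raise ValueError("exposure betas must be nonzero for ratio estimates")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        ratios = by / bx
        weights = bx**2 / se**2
        self.beta_ = weighted_median_point(ratios, weights)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxs = rng.normal(bx, se_x)
            bys = rng.normal(by, se)
            bxs[bxs == 0] = np.finfo(float).tiny
            boots[b] = weighted_median_point(bys / bxs, bxs**2 / se**2)
        self.se_ = float(np.std(boots, ddof=1))
        if self.se_ > 0:
            self.pval_ = float(2 * sps.norm.sf(abs(self.beta_ / self.se_)))
        else:
            self.pval_ = 0.0 if self.beta_ != 0 else 1.0
        self.ci_low_ = self.beta_ - _Z95 * self.se_
        self.ci_high_ = self.beta_ + _Z95 * self.se_
        self.n_snp_ = bx.size
        return self


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes, closed form from the full-sample sums."""
    sxx = w @ bx**2
    sxy = w @ (bx * by)
    denom = sxx - w * bx**2
    if np.any(denom <= 0):
        raise ValueError("leave-one-out slope undefined (single informative SNP)")
    return (sxy - w * bx * by) / denom


class MRPresso(BaseEstimator):
    """Residual-sum-of-squares outlier test for pleiotropic instruments.

    The observed statistic is RSS = sum_j w_j (by_j - b_{-j} bx_j)² with
    b_{-j} the leave-one-out IVW slope.  Its null distribution is simulated
    by drawing by*_j ~ N(b_{-j} bx_j, se_y_j) ``n_sim`` times and recomputing
    the statistic (including the leave-one-out slopes) on each draw; the
    global p-value is the add-one Monte-Carlo tail probability.  Per-SNP
    weighted squared residuals get the same treatment; SNPs whose
    Bonferroni-adjusted empirical p falls below ``outlier_alpha`` are flagged
    and the corrected estimate is IVW on the rest.
    """

    def __init__(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                 random_state: int | None = None):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.random_state = random_state

    def fit(self, X, y, se_y):
        bx = _as_1d(X, "X", 4)
        by = _as_1d(y, "y", 4)
        se = _check_se(_as_1d(se_y, "se_y", 4))
        if not (bx.size == by.size == se.size):
            raise ValueError("X, y, se_y must have equal length")
        if self.n_sim < 1:
            raise ValueError("n_sim must be a positive integer")
        j = bx.size
        w = 1.0 / se**2
        slopes = _loo_slopes(bx, by, w)
        obs_res = w * (by - slopes * bx) ** 2
        self.global_rss_ = float(obs_res.sum())

        rng = np.random.default_rng(self.random_state)
        by_sim = rng.normal(slopes * bx, se, size=(self.n_sim, j))
        sxx = w @ bx**2
        sxy_sim = by_sim @ (w * bx)  # (n_sim,)
        denom = sxx - w * bx**2  # (j,)
        slopes_sim = (sxy_sim[:, None] - (w * bx) * by_sim) / denom
        res_sim = w * (by_sim - slopes_sim * bx) ** 2  # (n_sim, j)
        rss_sim = res_sim.sum(axis=1)
        self.global_pval_ = float(
            (1 + np.sum(rss_sim >= self.global_rss_)) / (self.n_sim + 1))
        per_snp_p = (1 + np.sum(res_sim >= obs_res, axis=0)) / (self.n_sim + 1)
        self.outlier_pvals_ = per_snp_p
        self.outlier_mask_ = per_snp_p * j < self.outlier_alpha
        keep = ~self.outlier_mask_
        if keep.sum() >= 2:
            corrected = IVWRegression().fit(bx[keep], by[keep], se[keep])
        else:
            corrected = IVWRegression().fit(bx, by, se)
        self.corrected_ = corrected
        self.n_snp_ = j
        return self


class MVMRRegression(BaseEstimator):
    """Multivariable MR: joint WLS of SNP-outcome betas on K exposures.

    No intercept; weights 1/se_y².  Each coefficient is that exposure's
    effect on the outcome conditional on the others.  SEs use the unscaled
    WLS covariance times max(1, residual standard error); p-values are
    two-sided t on J - K degrees of freedom.
    """

    def fit(self, X, y, se_y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        by = _as_1d(y, "y", 2)
        se = _check_se(_as_1d(se_y, "se_y", 2))
        j, k = X.shape
        if j != by.size or j != se.size:
            raise ValueError("X, y, se_y must agree on SNP count")
        if j < k + 2:
            raise ValueError(f"need at least K + 2 = {k + 2} SNPs, got {j}")
        w = 1.0 / se**2
        xw = X * np.sqrt(w)[:, None]
        if np.linalg.matrix_rank(xw) < k:
            raise np.linalg.LinAlgError("rank-deficient exposure design (collinear betas)")
        res = sm.WLS(by, X, weights=w).fit()
        sigma = float(np.sqrt(res.scale))
        base_se = np.sqrt(np.diag(res.normalized_cov_params))
        scaled = base_se * max(1.0, sigma)
        df = j - k
        self.coef_ = np.asarray(res.params, float)
        self.se_ = scaled
        self.pval_ = 2 * sps.t.sf(np.abs(self.coef_ / scaled), df)
        tq = sps.t.ppf(0.975, df)
        self.ci_low_ = self.coef_ - tq * scaled
        self.ci_high_ = self.coef_ + tq * scaled
        self.scale_ = sigma
        self.df_ = df
        self.n_snp_ = j
        self.n_exposures_ = k
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_
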