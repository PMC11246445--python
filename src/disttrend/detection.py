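"""Detection-function fitting for line-transect distance sampling.

The detection model is the half-normal key with cosine adjustments,

    g(x) = exp(-x^2 / (2 sigma^2)) * [1 + sum_j a_j cos(j pi x / w)],

rescaled so that g(0) = 1, fitted to unbinned perpendicular distances on
[0, w] by maximising the exact continuous-data likelihood with density
f(x) = g(x) / int_0^w g(u) du.  The number of cosine terms (orders 2..J)
is selected by AIC against the key-only fit; candidates whose fitted g is
negative anywhere on [0, w] are rejected.  The average detection
probability within the truncation distance is P = (1/w) int_0^w g(x) dx,
and w * P is the effective strip half-width.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = ["truncate_distances", "HalfNormalCosineDetection",
           "fit_halfnormal_cosine", "ks_gof", "average_detection_prob"]

_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


def average_detection_prob(sigma: float, w: float, coeffs=(),
                           orders=()) -> float:
    """P = (1/w) int_0^w g(x) dx with g scaled so g(0) = 1.

    Deterministic 64-point Gauss-Legendre quadrature; strictly increasing
    in ``sigma`` for the key-only model.
    """
    nodes, wts = _gauss_legendre(0.0, w, 64)
    g0 = 1.0 + float(np.sum(coeffs))
    s = HalfNormalCosineDetection._shape(nodes, np.log(sigma),
                                         np.asarray(coeffs, float),
                                         tuple(orders), w)
    return float(wts @ s) / g0 / w


def truncate_distances(distances, fraction: float = 0.10):
    """Drop the farthest ``fraction`` of distances.

    Returns ``(kept, w)`` where ``w`` is the empirical ``1 - fraction``
    quantile (linear interpolation) and ``kept`` are all distances <= w.
    """
    x = np.asarray(distances, dtype=float)
    if x.size == 0:
        raise ValueError("no distances to truncate")
    if not 0.0 <= fraction < 0.5:
        raise ValueError("truncation fraction must be in [0, 0.5)")
    w = float(np.quantile(x, 1.0 - fraction))
    return x[x <= w], w


class HalfNormalCosineDetection(BaseEstimator):
    """Half-normal + cosine detection function fitted by maximum likelihood.

    Parameters
    ----------
    w : float
        Truncation distance in metres; ``np.inf`` fits the untruncated
        half-normal (key only, no adjustments possible).
    max_adjust_order : int
        Highest cosine order considered; candidate term sets are the
        nested {}, {2}, ..., {2..max_adjust_order}, compared by AIC.
    warn_threshold : int
        Emit a warning (do not fail) when fewer sightings enter the fit.

    Attributes
    ----------
    sigma_ : half-normal scale (m).
    cosine_coeffs_ : fitted adjustment coefficients (may be empty).
    orders_ : cosine orders matching ``cosine_coeffs_``.
    p_hat_ : average detection probability within ``w``.
    esw_ : effective strip half-width ``w * p_hat_`` (m).
    n_used_ : sightings entering the fit.
    log_likelihood_, aic_ : fit quality of the selected candidate.
    cv_p_ : delta-method CV of ``p_hat_`` from the observed information.
    """

    def __init__(self, w: float = np.inf, max_adjust_order: int = 3,
                 warn_threshold: int = 60):
        self.w = w
        self.max_adjust_order = max_adjust_order
        self.warn_threshold = warn_threshold

    @classmethod
    def from_params(cls, sigma: float, w: float, coeffs=(), orders=()):
        """Build a detection model with known parameters (no fitting).

        Useful for simulating from, or testing against, a fixed model.
        """
        self = cls(w=w)
        self.w_ = float(w)
        self.sigma_ = float(sigma)
        self.cosine_coeffs_ = np.asarray(coeffs, dtype=float)
        self.orders_ = tuple(orders)
        self.n_used_ = 0
        self.cv_p_ = 0.0
        if np.isinf(w):
            self.esw_ = self.sigma_ * _SQRT_HALF_PI
            self.p_hat_ = np.nan
        else:
            self.p_hat_ = average_detection_prob(sigma, w, coeffs, orders)
            self.esw_ = self.p_hat_ * w
        return self

    # -- shape evaluation ------------------------------------------------

    @staticmethod
    def _shape(x, log_sigma, coeffs, orders, w):
        """Unnormalised g with g(0) = 1 + sum(a_j)."""
        sigma = np.exp(log_sigma)
        s = np.exp(-np.asarray(x, float) ** 2 / (2.0 * sigma ** 2))
        if len(coeffs):
            adj = np.ones_like(s)
            for a, j in zip(coeffs, orders):
                adj = adj + a * np.cos(j * np.pi * np.asarray(x, float) / w)
            s = s * adj
        return s

    def _nll(self, theta, x, orders, nodes, wts):
        log_sigma, coeffs = theta[0], theta[1:]
        if np.isinf(self.w):
            sigma = np.exp(log_sigma)
            norm = sigma * _SQRT_HALF_PI
            return (np.sum(x ** 2) / (2.0 * sigma ** 2)
                    + x.size * np.log(norm))
        sx = self._shape(x, log_sigma, coeffs, orders, self.w)
        sq = self._shape(nodes, log_sigma, coeffs, orders, self.w)
        if np.any(sx <= 0.0) or np.any(sq < 0.0):
            return 1e10 + 1e6 * (np.sum(np.minimum(sx, 0.0) ** 2)
                                 + np.sum(np.minimum(sq, 0.0) ** 2))
        norm = float(wts @ sq)
        if not np.isfinite(norm) or norm <= 0:
            return 1e10
        return -float(np.sum(np.log(sx))) + x.size * np.log(norm)

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size and (np.any(x < 0) or np.any(x > self.w)):
            raise ValueError("distances must lie in [0, w]")
        if np.unique(x).size < 2:
            raise ValueError("need at least 2 distinct distances to fit")
        if x.size < self.warn_threshold:
            warnings.warn(
                f"only {x.size} sightings entered the detection fit; "
                f"fewer than the recommended {self.warn_threshold}",
                UserWarning, stacklevel=2)

        if np.isinf(self.w):
            nodes = wts = None
            candidate_orders = [()]
        else:
            nodes, wts = _gauss_legendre(0.0, self.w, 64)
            candidate_orders = [tuple(range(2, 2 + m))
                                for m in range(0, max(0, self.max_adjust_order - 1) + 1)]

        sigma0 = max(np.sqrt(np.mean(x ** 2)), 1e-6)
        best = None
        for orders in candidate_orders:
            res = self._fit_candidate(x, orders, sigma0, nodes, wts)
            if res is None:
                continue
            theta, nll = res
            aic = 2.0 * nll + 2.0 * (1 + len(orders))
            if best is None or aic < best[2]:
                best = (theta, nll, aic, orders)
        if best is None:
            raise RuntimeError("no valid detection-function candidate "
                               "(all fits non-finite or negative)")
        theta, nll, aic, orders = best
        self.sigma_ = float(np.exp(theta[0]))
        self.cosine_coeffs_ = np.asarray(theta[1:], dtype=float)
        self.orders_ = orders
        self.n_used_ = int(x.size)
        self.log_likelihood_ = -float(nll)
        self.aic_ = float(aic)
        self.w_ = float(self.w)

        if np.isinf(self.w):
            self.esw_ = self.sigma_ * _SQRT_HALF_PI
            self.p_hat_ = np.nan
        else:
            g0 = 1.0 + float(np.sum(self.cosine_coeffs_))
            sq = self._shape(nodes, theta[0], theta[1:], orders, self.w)
            self.esw_ = float(wts @ sq) / g0
            self.p_hat_ = self.esw_ / self.w
        self.cv_p_ = self._cv_p(theta, x, orders, nodes, wts)
        return self

    def _fit_candidate(self, x, orders, sigma0, nodes, wts):
        if not orders:
            # 1-D problem in log sigma: Brent to high precision
            f = lambda ls: self._nll(np.array([ls]), x, orders, nodes, wts)
            ls0 = np.log(sigma0)
            res = optimize.minimize_scalar(
                f, bounds=(ls0 - 8.0, ls0 + 8.0),
                method="bounded", options={"xatol": 1e-11})
            theta = np.array([res.x])
            nll = float(res.fun)
        else:
            theta0 = np.concatenate([[np.log(sigma0)], np.zeros(len(orders))])
            res = optimize.minimize(
                self._nll, theta0, args=(x, orders, nodes, wts),
                method="L-BFGS-B",
                options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500})
            theta, nll = res.x, float(res.fun)
        if not np.isfinite(nll) or nll >= 1e9:
            return None
        # reject candidates whose g is negative or non-monotone on [0, w]
        # (monotone non-increasing detection is the standard constraint
        # for adjustment-term fits)
        if not np.isinf(self.w):
            grid = np.linspace(0.0, self.w, 512)
            g0 = 1.0 + float(np.sum(theta[1:]))
            if g0 <= 0:
                return None
            g = self._shape(grid, theta[0], theta[1:], orders, self.w)
            if np.any(g < -1e-12):
                return None
            if orders and np.any(np.diff(g) > 1e-9 * g0):
                return None
        return theta, nll

    def _cv_p(self, theta, x, orders, nodes, wts):
        """Delta-method CV of P from the observed information matrix."""
        if np.isinf(self.w):
            # untruncated: var(sigma^2) = 2 sigma^4 / n; P undefined, use
            # the esw CV instead: esw prop. to sigma
            return 1.0 / np.sqrt(2.0 * x.size)
        h = 1e-4

        def p_of(t):
            g0 = 1.0 + float(np.sum(t[1:]))
            sq = self._shape(nodes, t[0], t[1:], orders, self.w)
            return float(wts @ sq) / g0 / self.w

        k = theta.size
        hess = np.empty((k, k))
        grad_p = np.empty(k)
        f0 = self._nll(theta, x, orders, nodes, wts)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h
            grad_p[i] = (p_of(theta + ei) - p_of(theta - ei)) / (2 * h)
            for j in range(i, k):
                ej = np.zeros(k)
                ej[j] = h
                hess[i, j] = hess[j, i] = (
                    self._nll(theta + ei + ej, x, orders, nodes, wts)
                    - self._nll(theta + ei - ej, x, orders, nodes, wts)
                    - self._nll(theta - ei + ej, x, orders, nodes, wts)
                    + self._nll(theta - ei - ej, x, orders, nodes, wts)
                ) / (4 * h * h)
        del f0
        try:
            cov = np.linalg.pinv(hess)
            var_p = float(grad_p @ cov @ grad_p)
        except np.linalg.LinAlgError:  # pragma: no cover
            return 0.0
        p = p_of(theta)
        if var_p <= 0 or p <= 0:
            return 0.0
        return float(np.sqrt(var_p) / p)

    # -- evaluation ------------------------------------------------------

    def detection_prob(self, x):
        """g(x), scaled so g(0) = 1."""
        g0 = 1.0 + float(np.sum(self.cosine_coeffs_))
        return self._shape(x, np.log(self.sigma_), self.cosine_coeffs_,
                           self.orders_, self.w_) / g0

    def cdf(self, x):
        """Model CDF of detected distances, F(x) = int_0^x g / int_0^w g."""
        if np.isinf(self.w_):
            from scipy.special import erf
            return erf(np.asarray(x, float) / (self.sigma_ * np.sqrt(2.0)))
        grid = np.linspace(0.0, self.w_, 4097)
        g = self.detection_prob(grid)
        cum = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2.0
                                               * np.diff(grid))])
        cum /= cum[-1]
        return np.interp(np.asarray(x, float), grid, cum)


def _gauss_legendre(a, b, n):
    nodes, wts = np.polynomial.legendre.leggauss(n)
    return (b - a) / 2.0 * (nodes + 1.0) + a, (b - a) / 2.0 * wts


def fit_halfnormal_cosine(distances, w: float,
                          max_adjust_order: int = 3) -> HalfNormalCosineDetection:
    """Functional wrapper: fit a detection function on ``[0, w]``."""
    return HalfNormalCosineDetection(
        w=w, max_adjust_order=max_adjust_order).fit(distances)


def ks_gof(fit: HalfNormalCosineDetection, distances):
    """One-sample Kolmogorov-Smirnov test of distances against the model.

    Returns ``(statistic, p_value)`` with the p-value from the asymptotic
    Kolmogorov distribution.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 distances for the KS test")
    if np.any(x < 0) or np.any(x > fit.w_):
        raise ValueError("distances must lie within [0, w]")
    res = stats.kstest(x, fit.cdf, method="asymp")
    return float(res.statistic), float(res.pvalue)
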