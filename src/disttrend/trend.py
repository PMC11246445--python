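"""Two-stage Monte-Carlo trend analysis of density time series.

Stage 1 propagates density-estimate uncertainty: each estimate's standard
deviation is recovered from its 95% confidence interval as
SD = (U - L) / (2 * 1.96) and 1000 replicate densities are drawn — from a
truncated normal on [L, U] for non-zero estimates, from a plain normal for
zero estimates.  A penalized cubic regression spline of density on year
with basis dimension 4 (smoothing parameter by generalized cross
validation) is fitted to the stacked replicate points of each series.
Stage 2 propagates trend-model uncertainty: per predicted year, 1000
values are drawn from N(D_predicted, SE) and their mean forms the trend
line, with 2.5/97.5 percentiles retained as a plotting ribbon.

Negative simulated or predicted densities are permitted (the normal
branches allow them) and reported as-is; display clipping is left to
plotting.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

from .simulate import SEASON_OFFSETS

logger = logging.getLogger("disttrend")

TREND_COLUMNS = ["area", "species", "season", "year", "d_predicted", "se",
                 "trend_line", "lo95", "hi95"]


def sd_from_ci(density: float, ci_low: float, ci_high: float) -> float:
    """Standard deviation implied by a 95% interval: (U - L) / (2 * 1.96)."""
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    return (ci_high - ci_low) / (2.0 * 1.96)


def simulate_replicates(density: float, ci_low: float, ci_high: float,
                        n_rep: int, rng) -> np.ndarray:
    """Stage-1 replicate densities for one estimate.

    Zero estimates use a normal distribution; non-zero estimates a normal
    truncated to [L, U].  A zero-width interval yields a constant vector.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    sd = sd_from_ci(density, ci_low, ci_high)
    if sd == 0.0:
        return np.full(n_rep, float(density))
    if density == 0.0:
        return rng.normal(0.0, sd, size=n_rep)
    a = (ci_low - density) / sd
    b = (ci_high - density) / sd
    return stats.truncnorm.rvs(a, b, loc=density, scale=sd, size=n_rep,
                               random_state=rng)


class PenalizedSplineTrend(BaseEstimator, RegressorMixin):
    """Penalized cubic regression spline of density on year.

    A B-spline basis of dimension ``k`` (cubic, equally spaced interior
    knots, none when ``k = 4``) is fitted by penalized least squares with
    an integrated-squared-second-derivative penalty; the smoothing
    parameter is chosen by generalized cross validation over a log-spaced
    grid.  As the penalty grows the fit shrinks toward a straight line
    (the penalty null space).  With ``k = 4`` the basis spans exactly the
    cubic polynomials over the year range.

    With fewer than 3 distinct years the model falls back to an
    unpenalized straight-line fit (logged); fewer than 2 distinct years is
    an error.  Prediction standard errors use the Bayesian posterior
    covariance ``sigma^2 (X'X + lam S)^{-1}``.
    """

    def __init__(self, k: int = 4, lam: float | str = "gcv",
                 lam_grid=None):
        self.k = k
        self.lam = lam
        self.lam_grid = lam_grid

    # -- basis helpers ---------------------------------------------------

    def _design(self, u: np.ndarray) -> np.ndarray:
        if self.linear_fallback_:
            return np.column_stack([np.ones_like(u), u])
        t = self._knots
        return np.column_stack([
            BSpline(t, np.eye(self.k)[i], 3, extrapolate=True)(u)
            for i in range(self.k)])

    def _penalty(self) -> np.ndarray:
        """Gram matrix of basis second derivatives (exact, Gauss 3-pt)."""
        t = self._knots
        spans = np.unique(t)
        nodes, wts = np.polynomial.legendre.leggauss(3)
        S = np.zeros((self.k, self.k))
        for a, b in zip(spans[:-1], spans[1:]):
            x = (b - a) / 2.0 * (nodes + 1.0) + a
            w = (b - a) / 2.0 * wts
            d2 = np.column_stack([
                BSpline(t, np.eye(self.k)[i], 3).derivative(2)(x)
                for i in range(self.k)])
            S += (d2 * w[:, None]).T @ d2
        return S

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        ux = np.unique(x)
        if ux.size < 2:
            raise ValueError("need at least 2 distinct years to fit a trend")
        self.x_min_, self.x_max_ = float(ux[0]), float(ux[-1])
        self.linear_fallback_ = ux.size < 3
        if self.linear_fallback_:
            logger.warning("trend series has %d distinct timepoints; "
                           "falling back to an unpenalized linear fit",
                           ux.size)
        else:
            n_interior = self.k - 4
            interior = (np.linspace(0, 1, n_interior + 2)[1:-1]
                        if n_interior > 0 else np.array([]))
            self._knots = np.concatenate([[0.0] * 4, interior, [1.0] * 4])

        # aggregate replicate points sharing a year: weighted normal equations
        u = (x - self.x_min_) / (self.x_max_ - self.x_min_)
        uu, inv = np.unique(u, return_inverse=True)
        m = np.bincount(inv).astype(float)
        sy = np.bincount(inv, weights=y)
        syy = float(y @ y)
        Xu = self._design(uu)
        XtWX = (Xu * m[:, None]).T @ Xu
        XtWy = Xu.T @ sy
        n = x.size

        if self.linear_fallback_:
            S = np.zeros((2, 2))
            lam = 0.0
            grid = [0.0]
        elif self.lam != "gcv":
            S = self._penalty()
            lam = float(self.lam)
            grid = [lam]
        else:
            S = self._penalty()
            grid = (np.asarray(self.lam_grid, float) if self.lam_grid
                    is not None else np.logspace(-7.0, 7.0, 57))
            if uu.size >= Xu.shape[1]:
                grid = np.concatenate([[0.0], grid])

        best = None
        for lam_c in grid:
            A = XtWX + lam_c * S
            try:
                beta = np.linalg.solve(A, XtWy)
                edf = float(np.trace(np.linalg.solve(A, XtWX)))
            except np.linalg.LinAlgError:
                continue
            rss = syy - 2.0 * beta @ XtWy + beta @ XtWX @ beta
            rss = max(rss, 0.0)
            gcv = n * rss / (n - edf) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam_c, beta, edf, rss)
        if best is None:
            raise RuntimeError("penalized spline fit failed for every "
                               "smoothing parameter")
        self.gcv_, self.lam_, self.coef_, self.edf_, rss = best
        self.sigma2_ = rss / max(n - self.edf_, 1.0)
        A = XtWX + self.lam_ * S
        self.cov_coef_ = self.sigma2_ * np.linalg.inv(A)
        return self

    def predict(self, X, return_se: bool = False):
        x = np.asarray(X, dtype=float).ravel()
        u = (x - self.x_min_) / (self.x_max_ - self.x_min_)
        Xp = self._design(u)
        mu = Xp @ self.coef_
        if not return_se:
            return mu
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xp,
                                          self.cov_coef_, Xp), 0.0))
        return mu, se


@dataclass
class ReplicateSeries:
    """Stage-1 Monte-Carlo ensemble attached to one density time series."""
    key: tuple[str, str, str]            # (area, species, season|"all")
    timepoints: np.ndarray               # decimal years, ordered
    observed: pd.DataFrame               # one density row per timepoint
    replicates: np.ndarray               # n_rep x T
    n_rep: int
    seed: int


@dataclass
class TrendModel:
    """Fitted smoother plus stage-2 prediction ensemble for one series."""
    key: tuple[str, str, str]
    years: np.ndarray
    d_predicted: np.ndarray
    se: np.ndarray
    smoother: PenalizedSplineTrend
    timepoints: np.ndarray
    observed: pd.DataFrame
    n_rep: int
    seed: int
    prediction_replicates: np.ndarray | None = field(default=None, repr=False)
    trend_line: np.ndarray | None = None
    lo95: np.ndarray | None = None
    hi95: np.ndarray | None = None


def _series_seed(master_seed: int, key) -> int:
    tag = zlib.crc32("|".join(map(str, key)).encode())
    # fold into a 31-bit seed, deterministic and order-independent
    return int(np.random.SeedSequence([int(master_seed), tag])
               .generate_state(1)[0] % (2 ** 31))


def build_series(density_table: pd.DataFrame, key, rows: pd.DataFrame,
                 n_rep: int, seed: int,
                 aggregated: bool = False) -> ReplicateSeries:
    """Assemble one ReplicateSeries from density-table rows."""
    rows = rows.copy()
    if aggregated:
        rows["timepoint"] = rows["year"] + rows["season"].map(SEASON_OFFSETS)
    else:
        rows["timepoint"] = rows["year"].astype(float)
    rows = rows.sort_values("timepoint", ignore_index=True)
    rng = np.random.default_rng(seed)
    reps = np.column_stack([
        simulate_replicates(r.density, r.ci_low, r.ci_high, n_rep, rng)
        for r in rows.itertuples()])
    return ReplicateSeries(key=key,
                           timepoints=rows["timepoint"].to_numpy(),
                           observed=rows, replicates=reps, n_rep=n_rep,
                           seed=seed)


def fit_trend(series: ReplicateSeries, basis_dim: int = 4) -> TrendModel:
    """Fit the penalized smooth of replicate density on year.

    The smoother is fitted to all stacked replicate points (n_rep x T
    observations); predictions with standard errors are produced on the
    integer-year grid spanning the series.
    """
    t = series.timepoints
    x = np.tile(t, (series.n_rep, 1)).ravel()
    y = series.replicates.ravel()
    sm = PenalizedSplineTrend(k=basis_dim).fit(x, y)
    years = np.arange(int(np.floor(t.min())), int(np.floor(t.max())) + 1,
                      dtype=float)
    mu, se = sm.predict(years, return_se=True)
    return TrendModel(key=series.key, years=years, d_predicted=mu, se=se,
                      smoother=sm, timepoints=t, observed=series.observed,
                      n_rep=series.n_rep, seed=series.seed)


def simulate_predictions(model: TrendModel, n_rep: int | None = None,
                         seed: int | None = None) -> TrendModel:
    """Stage 2: resample predictions and form the trend line.

    Per predicted year, ``n_rep`` values are drawn from
    N(D_predicted, SE); the per-year mean of the draws is the trend line
    and the 2.5/97.5 percentiles form the plotted ribbon.
    """
    n_rep = model.n_rep if n_rep is None else n_rep
    seed = model.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)
    draws = rng.normal(model.d_predicted, model.se,
                       size=(n_rep, model.years.size))
    model.prediction_replicates = draws
    model.trend_line = draws.mean(axis=0)
    model.lo95 = np.percentile(draws, 2.5, axis=0)
    model.hi95 = np.percentile(draws, 97.5, axis=0)
    return model


def run_all_series(density_table: pd.DataFrame,
                   aggregate_seasons: tuple[str, ...] = (),
                   n_rep: int = 1000, basis_dim: int = 4,
                   master_seed: int = 0,
                   min_timepoints: int = 2) -> dict:
    """Run both Monte-Carlo stages for every series in a density table.

    One series is built per area x species x season, except areas listed
    in ``aggregate_seasons``, whose surveys form a single all-seasons
    series on a decimal-year axis.  Series with fewer distinct timepoints
    than ``min_timepoints`` are skipped with a warning.  Results are
    reproducible from ``master_seed`` and independent of row order.
    """
    models: dict[tuple, TrendModel] = {}
    df = density_table.sort_values(["area", "species", "year", "season"],
                                   ignore_index=True)
    for (area, sp), sub in df.groupby(["area", "species"], sort=True):
        if area in aggregate_seasons:
            groups = [(("all"), sub)]
        else:
            groups = [(season, g) for season, g in
                      sub.groupby("season", sort=True)]
        for season, rows in groups:
            key = (area, sp, season)
            n_t = (rows["year"].astype(float)
                   + (rows["season"].map(SEASON_OFFSETS)
                      if area in aggregate_seasons else 0.0)).nunique()
            if n_t < min_timepoints:
                logger.warning("series %s has %d timepoint(s); skipped",
                               key, n_t)
                continue
            seed = _series_seed(master_seed, key)
            series = build_series(df, key, rows, n_rep, seed,
                                  aggregated=area in aggregate_seasons)
            model = fit_trend(series, basis_dim=basis_dim)
            simulate_predictions(model, n_rep, seed + 1)
            models[key] = model
    return models


def trend_table(models: dict) -> pd.DataFrame:
    """Flatten fitted TrendModels into the per-series trend table."""
    rows = []
    for (area, sp, season), m in sorted(models.items()):
        for i, yr in enumerate(m.years):
            rows.append((area, sp, season, int(yr), m.d_predicted[i],
                         m.se[i], m.trend_line[i], m.lo95[i], m.hi95[i]))
    return pd.DataFrame(rows, columns=TREND_COLUMNS)
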