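"""Post-stratified density estimation from line-transect surveys.

One detection function is fitted per area x species, pooling distances
across all seasons and years; densities are then computed per
season-year stratum from stratum counts and effort,

    D_ij = n_ij / (2 (w/1000) L_ij P),

in clusters per km^2, scaled to animals per km^2 by the stratum's mean
cluster size.  The variance combines the between-transect encounter-rate
variance, the delta-method variance of P and the cluster-size variance on
the CV^2 scale; 95% confidence intervals are log-normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .detection import (HalfNormalCosineDetection, fit_halfnormal_cosine,
                        ks_gof, truncate_distances)

logger = logging.getLogger("disttrend")

DENSITY_COLUMNS = ["area", "species", "year", "season", "n", "effort_km",
                   "w_m", "p_hat", "cluster_density", "mean_cluster_size",
                   "density", "se", "cv", "ci_low", "ci_high"]

_Z95 = 1.959963984540054


@dataclass
class DensityEstimate:
    """Post-stratified density for one area x species x year x season."""
    area: str
    species: str
    year: int
    season: str
    n: int
    effort_km: float
    w_m: float
    p_hat: float
    cluster_density: float
    mean_cluster_size: float
    density: float
    se: float
    cv: float
    ci_low: float
    ci_high: float


def pool_repeat_surveys(sightings: pd.DataFrame, effort: pd.DataFrame):
    """Sum effort and concatenate sightings over repeated surveys.

    Effort rows sharing (area, year, season, transect_id) are summed;
    sightings are kept as-is.  Idempotent on already-pooled tables.
    Raises ``KeyError`` if a sighting references a transect-occasion with
    no effort row.
    """
    keys = ["area", "year", "season", "transect_id"]
    pooled = (effort.groupby(keys, as_index=False)["length_km"].sum()
              .sort_values(keys, ignore_index=True))
    if len(sightings):
        have = set(map(tuple, pooled[keys].itertuples(index=False)))
        for row in sightings[keys].drop_duplicates().itertuples(index=False):
            if tuple(row) not in have:
                raise KeyError(
                    f"sighting on transect-occasion {tuple(row)} has no "
                    f"matching effort row")
    return sightings.reset_index(drop=True), pooled


def _encounter_rate_cv2(n_k: np.ndarray, l_k: np.ndarray) -> float:
    """CV^2 of the encounter rate n/L from between-transect variation.

    Uses the classic weighted between-transect estimator; with a single
    transect it falls back to Poisson counts (var(n) = n).
    """
    n = n_k.sum()
    L = l_k.sum()
    if n == 0:
        return 0.0
    K = len(l_k)
    if K < 2:
        return 1.0 / n
    er = n / L
    var_er = K / (L ** 2 * (K - 1)) * np.sum(l_k ** 2 * (n_k / l_k - er) ** 2)
    return float(var_er / er ** 2)


def _zero_estimate(area, species, year, season, effort_km) -> DensityEstimate:
    return DensityEstimate(area, species, int(year), season, 0,
                           float(effort_km), np.nan, np.nan, 0.0, np.nan,
                           0.0, 0.0, np.nan, 0.0, 0.0)


def estimate_stratum_density(fit: HalfNormalCosineDetection,
                             sightings: pd.DataFrame,
                             effort: pd.DataFrame,
                             key: tuple[str, str, int, str]) -> DensityEstimate:
    """Density estimate for one (area, species, year, season) stratum.

    ``fit`` must be the detection function pooled across seasons for the
    stratum's area x species; ``effort`` supplies the stratum's pooled
    transect rows.  Sightings beyond the truncation distance are excluded
    from the stratum count.
    """
    area, species, year, season = key
    eff = effort[(effort["area"] == area) & (effort["year"] == year)
                 & (effort["season"] == season)]
    L = float(eff["length_km"].sum())
    if L <= 0 or eff.empty:
        raise ValueError(f"no effort for stratum {key}")
    sgt = sightings[(sightings["area"] == area)
                    & (sightings["species"] == species)
                    & (sightings["year"] == year)
                    & (sightings["season"] == season)]
    if fit is not None:
        w = fit.w_
        if w <= 0:
            raise ValueError("truncation distance must be > 0")
        sgt = sgt[sgt["distance_m"] <= w]
    n = int(len(sgt))
    if n == 0:
        return _zero_estimate(area, species, year, season, L)
    if fit is None:
        raise ValueError(f"stratum {key} has sightings but no detection fit")

    cluster_density = n / (2.0 * (w / 1000.0) * L * fit.p_hat_)
    sizes = sgt["cluster_size"].to_numpy(dtype=float)
    mean_size = float(sizes.mean())
    density = cluster_density * mean_size

    counts = sgt.groupby("transect_id").size()
    n_k = np.array([counts.get(t, 0) for t in eff["transect_id"]], dtype=float)
    l_k = eff["length_km"].to_numpy(dtype=float)
    cv2 = _encounter_rate_cv2(n_k, l_k) + fit.cv_p_ ** 2
    if n >= 2 and mean_size > 0:
        cv2 += float(sizes.var(ddof=1)) / (mean_size ** 2 * n)
    cv = float(np.sqrt(cv2))
    se = density * cv
    c = float(np.exp(_Z95 * np.sqrt(np.log1p(cv2))))
    return DensityEstimate(area, species, int(year), season, n, L, w,
                           float(fit.p_hat_), float(cluster_density),
                           mean_size, float(density), float(se), cv,
                           float(density / c), float(density * c))


def estimate_all(sightings: pd.DataFrame, effort: pd.DataFrame,
                 truncation_fraction: float = 0.10,
                 max_adjust_order: int = 3,
                 species: list[str] | None = None,
                 return_fits: bool = False):
    """Full estimation pipeline: pool, truncate, fit, post-stratify.

    Emits one row per area x species x season-year combination present in
    the effort table (zero-density rows included).  With ``return_fits``
    also returns the per-(area, species) fitted detection functions.
    """
    sightings, effort = pool_repeat_surveys(sightings, effort)
    if species is None:
        species = sorted(sightings["species"].unique())
    rows = []
    fits: dict[tuple[str, str], HalfNormalCosineDetection | None] = {}
    for area in sorted(effort["area"].unique()):
        strata = (effort[effort["area"] == area][["year", "season"]]
                  .drop_duplicates().sort_values(["year", "season"]))
        for sp in species:
            mask = (sightings["area"] == area) & (sightings["species"] == sp)
            dists = sightings.loc[mask, "distance_m"].to_numpy(dtype=float)
            fit = None
            if np.unique(dists).size >= 2:
                kept, w = truncate_distances(dists, truncation_fraction)
                fit = fit_halfnormal_cosine(kept, w, max_adjust_order)
                ks_stat, ks_p = ks_gof(fit, kept)
                logger.info(
                    "detection fit %s/%s: n=%d w=%.1f sigma=%.1f orders=%s "
                    "AIC=%.1f P=%.3f KS D=%.3f p=%.3f", area, sp,
                    fit.n_used_, w, fit.sigma_, fit.orders_, fit.aic_,
                    fit.p_hat_, ks_stat, ks_p)
            elif dists.size:
                logger.warning("area %s species %s: %d sighting(s), too few "
                               "to fit a detection function; reporting zero "
                               "densities", area, sp, dists.size)
            fits[(area, sp)] = fit
            for year, season in strata.itertuples(index=False):
                if fit is None:
                    L = float(effort[(effort["area"] == area)
                                     & (effort["year"] == year)
                                     & (effort["season"] == season)]
                              ["length_km"].sum())
                    est = _zero_estimate(area, sp, year, season, L)
                else:
                    est = estimate_stratum_density(
                        fit, sightings, effort, (area, sp, int(year), season))
                rows.append(asdict(est))
    table = pd.DataFrame(rows, columns=DENSITY_COLUMNS)
    return (table, fits) if return_fits else table
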