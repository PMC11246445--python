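"""Initial/final window means and percent change per trend series.

Condenses each modeled time series into the mean trend-line density over
the first two and last two predicted years (or configured year windows)
and the percent change 100 * (final - initial) / initial between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("disttrend")

SUMMARY_COLUMNS = ["area", "species", "season", "initial_years",
                   "final_years", "initial_density", "final_density",
                   "percent_change"]


@dataclass
class ChangeSummary:
    key: tuple[str, str, str]
    initial_years: tuple[int, int]
    final_years: tuple[int, int]
    initial_density: float
    final_density: float
    percent_change: float


def window_means(model, initial_years, final_years):
    """Mean of the trend line over the initial and final year windows.

    ``model`` needs ``years`` and ``trend_line`` attributes (a fitted
    TrendModel or any namespace built from a trend table).
    """
    years = np.asarray(model.years, dtype=float)
    line = np.asarray(model.trend_line, dtype=float)

    def mean_over(window):
        vals = []
        for yr in window:
            idx = np.nonzero(years == float(yr))[0]
            if idx.size == 0:
                raise ValueError(
                    f"year {yr} outside the model's predicted range "
                    f"[{years.min():.0f}, {years.max():.0f}]")
            vals.append(line[idx[0]])
        return float(np.mean(vals))

    return mean_over(initial_years), mean_over(final_years)


def percent_change(initial_density: float, final_density: float) -> float:
    """100 * (final - initial) / initial; undefined (NaN) for initial = 0."""
    if initial_density == 0.0:
        logger.warning("percent change undefined for zero initial density")
        return float("nan")
    return 100.0 * (final_density - initial_density) / initial_density


def default_windows(model) -> tuple[tuple[int, int], tuple[int, int]]:
    """First-two / last-two predicted years of a series."""
    yrs = np.asarray(model.years, dtype=int)
    if yrs.size < 2:
        raise ValueError("series predicts fewer than 2 years")
    return (int(yrs[0]), int(yrs[min(1, yrs.size - 1)])), \
           (int(yrs[max(-2, -yrs.size)]), int(yrs[-1]))


def reference_windows() -> dict:
    """Year windows matching the reference scenario's survey calendar.

    Full-schedule units have season-specific windows (the dry season was
    not surveyed in the final year); the short and the season-aggregated
    series use their own survey spans.
    """
    win: dict = {}
    for area in ("TNP", "LMNP", "MR", "MGCA"):
        win[(area, "SR")] = ((2011, 2012), (2018, 2019))
        win[(area, "LR")] = ((2012, 2013), (2018, 2019))
        win[(area, "Dry")] = ((2012, 2013), (2017, 2018))
    for season in ("LR", "Dry", "SR", "all"):
        win[("RWMA", season)] = ((2012, 2013), (2014, 2015))
    win[("BWMA", "all")] = ((2011, 2012), (2017, 2018))
    return win


def summarize_all(models: dict, window_config: dict | None = None
                  ) -> pd.DataFrame:
    """One ChangeSummary row per fitted series.

    ``window_config`` maps (area, season) -> (initial_years, final_years);
    when ``None``, each series uses its first-two/last-two predicted
    years.  A configured run missing a series' window is an error naming
    the series.
    """
    rows = []
    for key in sorted(models):
        area, species, season = key
        model = models[key]
        if window_config is None:
            init_w, fin_w = default_windows(model)
        else:
            try:
                init_w, fin_w = window_config[(area, season)]
            except KeyError:
                raise KeyError(f"no year windows configured for series "
                               f"{key}") from None
        if max(init_w) >= min(fin_w):
            raise ValueError(f"initial years {init_w} must precede final "
                             f"years {fin_w} for series {key}")
        init_d, fin_d = window_means(model, init_w, fin_w)
        rows.append((area, species, season,
                     f"{init_w[0]}-{init_w[1]}", f"{fin_w[0]}-{fin_w[1]}",
                     init_d, fin_d, percent_change(init_d, fin_d)))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
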