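"""Per-series trend plots: observed estimates, ribbon, and trend line."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_series(model, path) -> None:
    """Plot one series: points with 95% CIs, percentile ribbon, trend line.

    Negative ribbon edges are clipped to zero for display only.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    obs = model.observed
    ax.errorbar(model.timepoints, obs["density"],
                yerr=[obs["density"] - obs["ci_low"],
                      obs["ci_high"] - obs["density"]],
                fmt="o", ms=4, color="0.3", ecolor="0.6", capsize=2,
                label="estimate (95% CI)")
    if model.trend_line is not None:
        lo = np.clip(model.lo95, 0.0, None)
        hi = np.clip(model.hi95, 0.0, None)
        ax.fill_between(model.years, lo, hi, alpha=0.25, color="tab:blue",
                        lw=0)
        ax.plot(model.years, np.clip(model.trend_line, 0.0, None),
                color="tab:blue", label="trend line")
    area, species, season = model.key
    ax.set_title(f"{area} / {species} / {season}")
    ax.set_xlabel("year")
    ax.set_ylabel("density (animals km$^{-2}$)")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
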