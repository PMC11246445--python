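import numpy as np
import pytest

from disttrend import SurveyDesign, TruthModel


@pytest.fixture
def flat_truth():
    """Constant-density truth: 5 clusters/km^2 of pairs, sigma 100 m."""
    return TruthModel(base_cluster_density=5.0, sigma_detect=100.0,
                      cluster_size_mean=2.0, w_max=300.0, ref_year=2011.0)


@pytest.fixture
def small_design():
    """One area, 10 x 2 km transects, 6 seasonal occasions over 2 years."""
    return SurveyDesign(
        areas=["A"],
        transects={"A": [(f"T{i}", 2.0) for i in range(10)]},
        schedule={"A": [(y, s) for y in (2011, 2012)
                        for s in ("LR", "Dry", "SR")]},
        seed=0)


def halfnormal_sample(rng, sigma, w, n):
    """Draw exactly n distances from the half-normal truncated at w."""
    out = np.empty(0)
    while out.size < n:
        x = np.abs(rng.normal(0.0, sigma, size=2 * n))
        out = np.concatenate([out, x[x <= w]])
    return out[:n]
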