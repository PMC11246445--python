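"""Two-stage Monte-Carlo trend machinery: SD-from-CI, truncated-normal
replicates, the penalized spline smoother and prediction resampling."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from disttrend import (PenalizedSplineTrend, ReplicateSeries, build_series,
                       fit_trend, run_all_series, sd_from_ci,
                       simulate_predictions, simulate_replicates, trend_table)


class TestSdFromCi:
    def test_printed_formula(self):
        assert sd_from_ci(5.0, 2.0, 10.0) == pytest.approx(8.0 / 3.92)

    def test_zero_width(self):
        assert sd_from_ci(3.0, 3.0, 3.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0), st.floats(0.001, 50.0))
    def test_symmetric_interval_inverts_to_sd(self, d, s):
        assert sd_from_ci(d, d - 1.96 * s, d + 1.96 * s) == \
            pytest.approx(s, rel=1e-12)

    def test_reversed_bounds_error(self):
        with pytest.raises(ValueError):
            sd_from_ci(5.0, 10.0, 2.0)


class TestStageOneReplicates:
    def test_truncnorm_containment_and_moments(self):
        rng = np.random.default_rng(0)
        d, lo, hi = 5.0, 2.0, 10.0
        reps = simulate_replicates(d, lo, hi, 1000, rng)
        assert reps.min() >= lo and reps.max() <= hi
        sd = sd_from_ci(d, lo, hi)
        a, b = (lo - d) / sd, (hi - d) / sd
        mean_true = stats.truncnorm.mean(a, b, loc=d, scale=sd)
        mc_se = reps.std(ddof=1) / np.sqrt(reps.size)
        assert abs(reps.mean() - mean_true) < 3.0 * mc_se

    def test_zero_density_uses_plain_normal(self):
        rng = np.random.default_rng(1)
        reps = simulate_replicates(0.0, -2.0, 2.0, 2000, rng)
        assert (reps < 0).any() and (reps > 0).any()
        assert abs(reps.std(ddof=1) - 4.0 / 3.92) < 0.05

    def test_degenerate_interval_gives_constants(self):
        assert (simulate_replicates(0.0, 0.0, 0.0, 100, 7) == 0.0).all()
        assert (simulate_replicates(4.0, 4.0, 4.0, 100, 7) == 4.0).all()

    def test_seed_determinism(self):
        r1 = simulate_replicates(5.0, 2.0, 10.0, 500, 42)
        r2 = simulate_replicates(5.0, 2.0, 10.0, 500, 42)
        np.testing.assert_array_equal(r1, r2)


class TestPenalizedSpline:
    def test_constant_input_reproduced(self):
        x = np.repeat(np.arange(2011.0, 2019.0), 100)
        y = np.full_like(x, 7.5)
        m = PenalizedSplineTrend(k=4).fit(x, y)
        mu, se = m.predict(np.arange(2011.0, 2019.0), return_se=True)
        np.testing.assert_allclose(mu, 7.5, atol=1e-6)
        assert np.all(se < 1e-6)

    def test_unpenalized_k4_equals_cubic_ols(self):
        """With no interior knots the k=4 basis spans the cubics, so the
        lam=0 fit must equal ordinary cubic polynomial regression."""
        rng = np.random.default_rng(8)
        x = np.repeat(np.arange(2011.0, 2020.0), 50)
        y = 3.0 + 0.5 * (x - 2015) + rng.normal(0, 1, x.size)
        m = PenalizedSplineTrend(k=4, lam=0.0).fit(x, y)
        grid = np.linspace(2011.0, 2019.0, 23)
        # polyfit on raw years is poorly conditioned; agreement to ~1e-5
        coef = np.polyfit(x, y, 3)
        np.testing.assert_allclose(m.predict(grid), np.polyval(coef, grid),
                                   rtol=1e-5, atol=1e-5)

    def test_linear_trend_matches_ols_line(self):
        rng = np.random.default_rng(9)
        years = np.arange(2011.0, 2020.0)
        x = np.repeat(years, 200)
        y = 10.0 + 0.6 * (x - 2011.0) + rng.normal(0, 0.8, x.size)
        m = PenalizedSplineTrend(k=4).fit(x, y)
        slope, icpt = np.polyfit(x, y, 1)
        ols_pred = icpt + slope * years
        resid = y - (icpt + slope * x)
        s2 = resid @ resid / (x.size - 2)
        se_line = np.sqrt(s2 * (1.0 / x.size + (years - x.mean()) ** 2
                                / np.sum((x - x.mean()) ** 2)))
        assert np.all(np.abs(m.predict(years) - ols_pred) <= 2.0 * se_line)

    def test_stacked_row_permutation_invariance(self):
        rng = np.random.default_rng(10)
        x = np.repeat(np.arange(2011.0, 2018.0), 80)
        y = np.sin((x - 2011.0) / 2.0) + rng.normal(0, 0.3, x.size)
        m1 = PenalizedSplineTrend(k=4).fit(x, y)
        perm = rng.permutation(x.size)
        m2 = PenalizedSplineTrend(k=4).fit(x[perm], y[perm])
        np.testing.assert_allclose(m1.coef_, m2.coef_, rtol=1e-10)

    def test_two_distinct_years_linear_fallback(self, caplog):
        x = np.array([2011.0] * 50 + [2014.0] * 50)
        y = np.array([1.0] * 50 + [4.0] * 50)
        with caplog.at_level("WARNING", logger="disttrend"):
            m = PenalizedSplineTrend(k=4).fit(x, y)
        assert m.linear_fallback_
        assert "linear" in caplog.text
        np.testing.assert_allclose(m.predict([2011.0, 2014.0]), [1.0, 4.0],
                                   atol=1e-8)

    def test_single_year_errors(self):
        with pytest.raises(ValueError):
            PenalizedSplineTrend().fit([2011.0, 2011.0], [1.0, 2.0])

    def test_matches_mgcv_cubic_regression_spline(self, tmp_path):
        """Independent cross-check against R mgcv's gam(y ~ s(x, k=4))."""
        rng = np.random.default_rng(42)
        x = np.repeat(np.arange(2011.0, 2020.0), 200)
        true = 10 + 0.8 * (x - 2011) - 0.05 * (x - 2011) ** 2
        y = true + rng.normal(0, 1.5, x.size)
        df = pd.DataFrame({"x": x, "y": y})
        df.to_csv(tmp_path / "xy.csv", index=False)
        rcode = (
            'suppressMessages(library(mgcv));'
            f'd <- read.csv("{tmp_path / "xy.csv"}");'
            'm <- gam(y ~ s(x, k=4, bs="cr"), data=d, method="GCV.Cp");'
            'p <- predict(m, newdata=data.frame(x=2011:2019), se.fit=TRUE);'
            'cat(sprintf("%.8f %.8f\\n", p$fit, p$se.fit))')
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        ref = np.array([[float(v) for v in line.split()]
                        for line in out.stdout.strip().splitlines()])
        m = PenalizedSplineTrend(k=4).fit(x, y)
        mu, se = m.predict(np.arange(2011.0, 2020.0), return_se=True)
        assert np.max(np.abs(mu - ref[:, 0])) < 0.15
        assert np.all((se / ref[:, 1] > 0.5) & (se / ref[:, 1] < 2.0))


def _toy_series(n_rep=200, seed=3, density=None):
    years = np.arange(2011, 2019)
    density = np.full(years.size, 6.0) if density is None else density
    table = pd.DataFrame({
        "area": "A", "species": "sp", "season": "Dry", "year": years,
        "density": density, "ci_low": density * 0.7,
        "ci_high": density * 1.4,
    })
    return build_series(table, ("A", "sp", "Dry"), table, n_rep, seed)


class TestTrendPipeline:
    def test_replicates_contained_in_intervals(self):
        s = _toy_series()
        lo = s.observed["ci_low"].to_numpy()
        hi = s.observed["ci_high"].to_numpy()
        assert np.all(s.replicates >= lo) and np.all(s.replicates <= hi)
        assert s.replicates.shape == (200, 8)
        assert np.isfinite(s.replicates).all()

    def test_constant_series_yields_flat_trend(self):
        model = fit_trend(_toy_series(), basis_dim=4)
        spread = model.d_predicted.max() - model.d_predicted.min()
        assert spread < 0.5  # flat within stage-1 noise
        model = simulate_predictions(model, 500, seed=1)
        assert np.all(model.lo95 <= model.trend_line)
        assert np.all(model.trend_line <= model.hi95)

    def test_prediction_resampling_moments_and_determinism(self):
        model = fit_trend(_toy_series(), basis_dim=4)
        m1 = simulate_predictions(model, 1000, seed=5)
        line1 = m1.trend_line.copy()
        bound = 3.0 * m1.se / np.sqrt(1000)
        assert np.all(np.abs(line1 - m1.d_predicted) <= bound + 1e-12)
        m2 = simulate_predictions(model, 1000, seed=5)
        np.testing.assert_array_equal(line1, m2.trend_line)

    def test_zero_se_predictions_are_exact(self):
        model = fit_trend(_toy_series(), basis_dim=4)
        model.se = np.zeros_like(model.se)
        model = simulate_predictions(model, 100, seed=2)
        np.testing.assert_allclose(model.trend_line, model.d_predicted,
                                   rtol=1e-12)

    def test_run_all_series_row_order_invariance(self):
        years = np.arange(2011, 2019)
        rows = []
        for season in ("LR", "Dry", "SR"):
            for y in years:
                d = 5.0 + 0.2 * (y - 2011)
                rows.append(("A", "sp", int(y), season, d, d * 0.8, d * 1.3))
        table = pd.DataFrame(rows, columns=["area", "species", "year",
                                            "season", "density", "ci_low",
                                            "ci_high"])
        t1 = trend_table(run_all_series(table, n_rep=100, master_seed=7))
        shuffled = table.sample(frac=1.0, random_state=1)
        t2 = trend_table(run_all_series(shuffled, n_rep=100, master_seed=7))
        pd.testing.assert_frame_equal(t1, t2)

    def test_aggregated_area_forms_single_series(self):
        rows = []
        for y, s in [(2011, "SR"), (2012, "Dry"), (2013, "LR"),
                     (2014, "SR"), (2015, "Dry"), (2017, "LR"),
                     (2018, "Dry")]:
            rows.append(("B", "sp", y, s, 4.0, 3.0, 5.5))
        table = pd.DataFrame(rows, columns=["area", "species", "year",
                                            "season", "density", "ci_low",
                                            "ci_high"])
        models = run_all_series(table, aggregate_seasons=("B",), n_rep=100,
                                master_seed=0)
        assert list(models) == [("B", "sp", "all")]
        model = models[("B", "sp", "all")]
        assert model.years[0] == 2011.0 and model.years[-1] == 2018.0
        # decimal-year axis with season offsets
        assert np.all(model.timepoints % 1 > 0)

    def test_short_series_skipped_with_warning(self, caplog):
        table = pd.DataFrame([("A", "sp", 2011, "Dry", 5.0, 4.0, 6.0)],
                             columns=["area", "species", "year", "season",
                                      "density", "ci_low", "ci_high"])
        with caplog.at_level("WARNING", logger="disttrend"):
            models = run_all_series(table, n_rep=50, master_seed=0)
        assert models == {}
        assert "skipped" in caplog.text
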