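"""Correlation framework: coefficients, dispatch, regressions, AIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import norm

from morphocline import clinestats as cs
from morphocline.synth import ClineParams, gen_cline_matrix


class TestBinLatitude:
    @pytest.mark.parametrize(
        "lat,expected",
        [(3.5, 0), (0.0, 0), (-3.0, 1), (-12.0, 2), (-15.0, 2), (-20.3, 3),
         (-7.5, 1)],  # the unassigned printed gap folds into band 1
    )
    def test_band_assignment(self, lat, expected):
        assert cs.bin_latitude(lat) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.bin_latitude(-95.0)

    def test_environment_vector_checks_consistency(self):
        with pytest.raises(ValueError):
            cs.EnvironmentVector("x", 100.0, -12.0, latitude_bin=0)
        ev = cs.EnvironmentVector("x", 100.0, -12.0)
        assert ev.latitude_bin == 2


class TestPointBiserial:
    def test_textbook_example(self):
        r = cs.point_biserial([1, 2, 3, 4], [0, 0, 1, 1])
        assert r == pytest.approx(0.8944, abs=1e-4)

    def test_equals_pearson_on_01_recode(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.integers(0, 2, size=30)
            if len(np.unique(y)) < 2:
                continue
            assert cs.point_biserial(x, y) == pytest.approx(
                stats.pearsonr(x, y)[0]
            )

    def test_perfect_separation_is_extreme(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        r = cs.point_biserial(x, [0, 0, 1, 1])
        assert abs(r) == pytest.approx(np.sqrt(np.mean(np.abs(x)) ** 2 /
                                               np.mean(x**2)))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            cs.point_biserial([1, 1, 1, 1], [0, 0, 1, 1])

    def test_non_binary_y_rejected(self):
        with pytest.raises(ValueError):
            cs.point_biserial([1, 2, 3], [0, 1, 2])


def simulate_polyserial(rho, n, k, seed):
    """Latent bivariate normal thresholded into k ordinal states."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    latent = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    tau = norm.ppf(np.arange(1, k) / k)
    return x, np.searchsorted(tau, latent)


class TestPolyserial:
    def test_null_case_estimates_near_zero(self):
        x, y = simulate_polyserial(0.0, 500, 3, seed=2)
        assert abs(cs.polyserial_ml(x, y)) < 0.15

    def test_recovers_generating_rho(self):
        x, y = simulate_polyserial(0.6, 10000, 4, seed=3)
        assert 0.55 <= cs.polyserial_ml(x, y) <= 0.65

    def test_binary_case_agrees_with_two_step_biserial(self):
        x, y = simulate_polyserial(0.5, 2000, 2, seed=4)
        res = cs.polyserial_ml(x, y, full=True)
        assert res["rho"] == pytest.approx(res["rho_two_step"], abs=0.02)

    def test_two_step_and_ml_agree_on_clean_data(self):
        for rho in (0.2, 0.6):
            x, y = simulate_polyserial(rho, 2000, 3, seed=int(rho * 10))
            res = cs.polyserial_ml(x, y, full=True)
            assert res["rho"] == pytest.approx(res["rho_two_step"], abs=0.02)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            cs.polyserial_ml([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 1, 1, 1])

    def test_estimate_stays_inside_unit_interval(self):
        # near-perfect ordering pushes rho toward 1 but never past it
        x = np.linspace(-3, 3, 60)
        y = np.digitize(x, [-1, 1])
        rho = cs.polyserial_ml(x, y)
        assert -1 < rho < 1 and rho > 0.9


class TestCramersV:
    def test_identity_association_is_one(self):
        x = [0, 0, 1, 1, 2, 2, 0, 1, 2]
        assert cs.cramers_v(x, x) == pytest.approx(1.0)

    def test_diagonal_table_is_one(self):
        x = [0] * 10 + [1] * 10
        y = [0] * 10 + [1] * 10
        assert cs.cramers_v(x, y) == pytest.approx(1.0)

    def test_balanced_independent_table_is_zero(self):
        x = [0, 0, 1, 1] * 5
        y = [0, 1, 0, 1] * 5
        assert cs.cramers_v(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_correction_shrinks_weak_association(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 30)
        y = rng.integers(0, 4, 30)
        assert cs.cramers_v(x, y, corrected=True) <= cs.cramers_v(x, y) + 1e-12

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            cs.cramers_v([0, 0, 0], [0, 1, 2])


class TestSeries:
    def make_synthetic(self, seed=0, n=600):
        params = ClineParams(
            n_specimens=n,
            latent_rho=(0.0, 0.4, 0.7),
            n_ordinal_states=(3, 3, 4),
            noise_sd=5.0,
            missing_rate=0.0,
            seed=seed,
        )
        df, truth = gen_cline_matrix(params)
        return df, truth

    def test_dispatch_methods_by_variable_kind(self, ingroup):
        chars = [c for c in ingroup.columns if c.startswith("char_")]
        env = ingroup.rename(
            columns={"altitude_m": "altitude", "latitude_deg": "latitude"}
        )
        series = cs.correlate_with_environment(
            ingroup[chars], env, target="altitude",
            kinds={c: "categorical" for c in chars},
        )
        methods = {e.variable_id: e.method for e in series.entries}
        n_states = {c: ingroup[c].nunique() for c in chars}
        for c in chars:
            expected = "point_biserial" if n_states[c] == 2 else "polyserial"
            assert methods[c] == expected

    def test_series_average_recovers_generating_rho(self):
        df, truth = self.make_synthetic(seed=5)
        chars = [c for c in df.columns if c.startswith("char_")]
        env = df.rename(columns={"altitude_m": "altitude",
                                 "latitude_deg": "latitude"})
        series = cs.correlate_with_environment(
            df[chars], env, "altitude", kinds={c: "categorical" for c in chars}
        )
        coefs = {e.variable_id: e.coefficient for e in series.entries}
        se = 1 / np.sqrt(len(df) - 3)  # Fisher-z scale approximation
        for j, rho in enumerate(truth["latent_rho"]):
            assert abs(abs(coefs[f"char_{j:02d}"]) - abs(rho)) < 3 * se + 0.02

    def test_series_average_monotone_in_generating_rho(self):
        avgs = []
        for rho in (0.1, 0.45, 0.8):
            params = ClineParams(
                n_specimens=500, latent_rho=(rho,) * 3,
                n_ordinal_states=(3, 3, 3), seed=11,
            )
            df, _ = gen_cline_matrix(params)
            chars = [c for c in df.columns if c.startswith("char_")]
            env = df.rename(columns={"altitude_m": "altitude",
                                     "latitude_deg": "latitude"})
            s = cs.correlate_with_environment(
                df[chars], env, "altitude",
                kinds={c: "categorical" for c in chars},
            )
            avgs.append(s.average)
        assert avgs[0] < avgs[1] < avgs[2]

    def test_average_is_sorting_invariant(self):
        df, _ = self.make_synthetic(seed=6, n=200)
        chars = [c for c in df.columns if c.startswith("char_")]
        env = df.rename(columns={"altitude_m": "altitude",
                                 "latitude_deg": "latitude"})
        s = cs.correlate_with_environment(
            df[chars], env, "altitude", kinds={c: "categorical" for c in chars}
        )
        assert s.average == pytest.approx(
            np.mean(sorted(np.abs([e.coefficient for e in s.entries])))
        )

    def test_constant_variable_reported_undefined(self):
        df = pd.DataFrame({"v": [1, 1, 1, 1]})
        env = pd.DataFrame(
            {"altitude": [1.0, 2.0, 3.0, 4.0], "latitude": [0.0] * 4}
        )
        s = cs.correlate_with_environment(df, env, "altitude",
                                          kinds={"v": "categorical"})
        assert np.isnan(s.entries[0].coefficient)
        assert s.entries[0].method == "undefined"

    def test_compare_series_identity_and_arithmetic(self):
        df, _ = self.make_synthetic(seed=7, n=100)
        chars = [c for c in df.columns if c.startswith("char_")]
        env = df.rename(columns={"altitude_m": "altitude",
                                 "latitude_deg": "latitude"})
        s = cs.correlate_with_environment(
            df[chars], env, "altitude", kinds={c: "categorical" for c in chars}
        )
        assert cs.compare_series(s, s)["difference"] == 0.0
        a = cs.CorrelationSeries("x", [cs.SeriesEntry("u", "pearson", 0.5, 10)])
        b = cs.CorrelationSeries("y", [cs.SeriesEntry("v", "pearson", -0.3, 10)])
        assert cs.compare_series(a, b)["difference"] == pytest.approx(0.2)


class TestBrightnessFits:
    def test_exact_line_is_certain(self):
        alt = np.linspace(0, 1000, 20)
        bright = pd.DataFrame({"area1": 0.8 - 0.0002 * alt})
        env = pd.DataFrame({"altitude": alt, "latitude": np.zeros(20)})
        (fit,) = cs.brightness_altitude_fits(bright, env)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-20
        assert fit.slope == pytest.approx(-0.0002)

    def test_constructed_negative_areas_are_detected(self):
        rng = np.random.default_rng(9)
        alt = rng.uniform(0, 1100, 45)
        cols = {}
        for i in range(7):  # strong negative slopes
            cols[f"neg{i}"] = 0.8 - 0.0004 * alt + rng.normal(0, 0.02, 45)
        for i in range(20):  # flat areas
            cols[f"flat{i}"] = 0.5 + rng.normal(0, 0.02, 45)
        env = pd.DataFrame({"altitude": alt, "latitude": np.zeros(45)})
        fits = cs.brightness_altitude_fits(pd.DataFrame(cols), env)
        signif_neg = [f.variable_id for f in fits
                      if f.p_value < 0.05 and f.slope < 0]
        assert sorted(signif_neg) == sorted(f"neg{i}" for i in range(7))

    def test_results_sorted_most_decreasing_first(self):
        alt = np.linspace(0, 1000, 10)
        bright = pd.DataFrame({
            "up": 0.2 + 0.0003 * alt,
            "down": 0.9 - 0.0005 * alt,
        })
        env = pd.DataFrame({"altitude": alt, "latitude": np.zeros(10)})
        fits = cs.brightness_altitude_fits(bright, env)
        assert [f.variable_id for f in fits] == ["down", "up"]

    def test_sparse_area_skipped_with_warning(self):
        bright = pd.DataFrame({"a": [0.5, np.nan, np.nan, np.nan]})
        env = pd.DataFrame({"altitude": [1.0, 2, 3, 4], "latitude": [0.0] * 4})
        with pytest.warns(UserWarning):
            fits = cs.brightness_altitude_fits(bright, env)
        assert fits == []

    def test_null_slope_type_one_error_rate(self):
        """Under no cline the slope test rejects ~5% of the time at alpha=.05."""
        rng = np.random.default_rng(10)
        alt = rng.uniform(0, 1000, 30)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = rng.normal(0.5, 0.05, 30)
            res = stats.linregress(alt, y)
            rejections += res.pvalue < 0.05
        # binomial 99.7% band around 0.05 with n=1000
        assert abs(rejections / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestAICCompare:
    def test_exact_linear_ranks_linear_first(self):
        x = np.linspace(0, 10, 40)
        y = 2.0 + 0.5 * x
        ranked = cs.aic_model_compare(x, y)
        assert ranked[0][0] == "linear"

    def test_exact_quadratic_ranks_quadratic_first(self):
        x = np.linspace(-5, 5, 200)
        y = 1.0 + 0.3 * x + 0.8 * x**2
        ranked = cs.aic_model_compare(x, y, models=("linear", "quadratic"))
        assert ranked[0][0] == "quadratic"

    def test_noisy_linear_prefers_linear_over_cubic(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 10, 300)
        y = 1 + 2 * x + rng.normal(0, 0.5, 300)
        ranked = cs.aic_model_compare(x, y, models=("linear", "cubic"))
        assert ranked[0][0] == "linear"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cs.aic_model_compare([1, 2, 3], [1, 2, 3])
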