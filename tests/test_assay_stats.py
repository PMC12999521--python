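import numpy as np
import pandas as pd
import pytest

from thermotree.assay_stats import (
    fit_elevation_trend,
    observer_anova,
    shock_effect,
    summarize_plots,
    thermal_range_and_margin,
)
from thermotree.errors import DegenerateDesignError, MissingMetadataError


def make_records(values, direction="ctmax", plot="P01", elevation=300.0,
                 shocked="no", observer="obs1"):
    return pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(len(values))],
            "plot_id": plot,
            "elevation": elevation,
            "direction": direction,
            "shocked": shocked,
            "observer": observer,
            "ct_value": values,
        }
    )


NORMALS = pd.DataFrame(
    {"plot_id": ["P01"], "elevation": [300.0], "bio1": [24.3], "bio5": [30.0]}
)


class TestSummarizePlots:
    def test_single_record_all_statistics_collapse(self):
        out = summarize_plots(make_records([42.0]), NORMALS)
        row = out.iloc[0]
        assert row["mean"] == row["median"] == row["q10"] == row["q25"] == 42.0
        assert row["n"] == 1

    def test_median_of_five(self):
        out = summarize_plots(make_records([40, 41, 42, 43, 44]), NORMALS)
        assert out.iloc[0]["median"] == 42.0

    def test_lowland_quantile_layout(self):
        """A lowland community built to have 10/25/50% quantiles 40/41/42."""
        rng = np.random.default_rng(0)
        # piecewise-uniform sample whose empirical quantiles land on the grid
        vals = np.concatenate(
            [
                np.full(110, 40.0),
                np.full(150, 41.0),
                np.full(250, 42.0),
                rng.uniform(42.5, 46.0, 490),
            ]
        )
        out = summarize_plots(make_records(vals), NORMALS)
        row = out.iloc[0]
        assert row["q10"] == pytest.approx(40.0)
        assert row["q25"] == pytest.approx(41.0)
        assert row["median"] == pytest.approx(42.0)

    def test_quantile_ordering_invariant(self):
        rng = np.random.default_rng(1)
        out = summarize_plots(make_records(rng.normal(42, 2, 200)), NORMALS)
        row = out.iloc[0]
        assert row["q10"] <= row["q25"] <= row["median"]

    def test_permutation_invariance(self):
        vals = list(np.random.default_rng(2).normal(42, 2, 50))
        a = summarize_plots(make_records(vals), NORMALS)
        b = summarize_plots(make_records(vals[::-1]), NORMALS)
        pd.testing.assert_frame_equal(
            a.drop(columns=[]), b, check_exact=False
        )

    def test_missing_normals_lists_plots(self):
        with pytest.raises(MissingMetadataError, match="P99"):
            summarize_plots(make_records([42.0], plot="P99"), NORMALS)


class TestElevationTrend:
    def test_spline_reproduces_exact_line(self):
        x = np.linspace(0, 3000, 30)
        y = 45.0 - 0.002 * x
        fit = fit_elevation_trend(x, y, "spline_k5")
        np.testing.assert_allclose(
            fit.grid_y, 45.0 - 0.002 * fit.grid_x, atol=1e-6
        )

    def test_constant_y_zero_slope(self):
        x = np.linspace(0, 1000, 10)
        fit = fit_elevation_trend(x, np.full(10, 42.0), "linear")
        assert fit.slope == 0.0
        assert fit.fvalue == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_elevation_trend(np.full(10, 5.0), np.arange(10.0), "linear")

    def test_linear_slope_matches_spline_mean_derivative(self):
        x = np.linspace(0, 2500, 40)
        rng = np.random.default_rng(3)
        y = 44.0 - 0.0023 * x + rng.normal(0, 0.2, 40)
        lin = fit_elevation_trend(x, y, "linear")
        spl = fit_elevation_trend(x, y, "spline_k5")
        mean_deriv = np.gradient(spl.grid_y, spl.grid_x).mean()
        assert lin.slope == pytest.approx(mean_deriv, abs=1e-3)

    def test_mat_slope_recovery(self):
        """Record-level regression recovers a CT_max-vs-MAT slope of 0.41."""
        from thermotree.synthdata import simulate_community_assays

        plots = pd.DataFrame(
            {
                "plot_id": [f"P{k}" for k in range(8)],
                "elevation": np.linspace(250, 3000, 8),
                "mat": np.linspace(24.0, 8.0, 8),
            }
        )
        slopes = []
        for rep in range(20):
            rec = simulate_community_assays(
                plots, 0.41, 32.0, sd=1.5, n_per_plot=40, seed=rep
            )
            fit = fit_elevation_trend(
                rec["mat"].to_numpy(), rec["ct_value"].to_numpy(), "linear"
            )
            slopes.append(fit.slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.41) < max(3 * se, 0.01)


class TestRangeAndMargin:
    def test_range_and_margins(self, assay_records, plot_normals):
        summaries = summarize_plots(assay_records, plot_normals)
        out = thermal_range_and_margin(summaries).set_index("plot_id")
        hot = summaries[(summaries["plot_id"] == "P01")
                        & (summaries["direction"] == "ctmax")].iloc[0]
        cold = summaries[(summaries["plot_id"] == "P01")
                         & (summaries["direction"] == "ctmin")].iloc[0]
        assert out.loc["P01", "range"] == pytest.approx(
            hot["mean"] - cold["mean"]
        )
        assert out.loc["P01", "margin_bio1"] == pytest.approx(
            hot["mean"] - 24.3
        )
        assert out.loc["P01", "margin_bio5"] == pytest.approx(
            hot["mean"] - 30.0
        )

    def test_plot_missing_direction_skipped(self):
        summaries = summarize_plots(make_records([42.0] * 5), NORMALS)
        with pytest.warns(UserWarning, match="ctmin"):
            out = thermal_range_and_margin(summaries)
        assert np.isnan(out.iloc[0]["range"])

    def test_null_range_trend_type_I_error(self):
        """With no generative trend, the range-vs-elevation slope is flat."""
        rng = np.random.default_rng(4)
        rejections = 0
        reps = 60
        for _ in range(reps):
            elev = np.linspace(200, 2800, 12)
            ranges = 36.0 + rng.normal(0, 1.0, 12)
            fit = fit_elevation_trend(elev, ranges, "linear")
            rejections += fit.pvalue < 0.05
        assert rejections / reps <= 0.10


class TestShockEffect:
    def test_ctmax_sign_convention(self):
        rec = pd.concat(
            [
                make_records([42.0] * 5, shocked="no"),
                make_records([41.0] * 5, shocked="yes"),
            ]
        )
        out = shock_effect(rec)
        assert out.iloc[0]["effect_c"] == pytest.approx(-1.0)
        assert out.iloc[0]["band"] == "low"

    def test_ctmin_reversed_convention(self):
        rec = pd.concat(
            [
                make_records([5.0] * 5, direction="ctmin", shocked="no"),
                make_records([4.0] * 5, direction="ctmin", shocked="yes"),
            ]
        )
        out = shock_effect(rec)
        assert out.iloc[0]["effect_c"] == pytest.approx(1.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        rec = pd.concat(
            [
                make_records(rng.normal(42, 1, 30), shocked="no"),
                make_records(rng.normal(41, 1, 30), shocked="yes"),
            ]
        )
        shifted = rec.assign(ct_value=rec["ct_value"] + 7.5)
        pd.testing.assert_frame_equal(shock_effect(rec), shock_effect(shifted))

    def test_band_assignment_half_open(self):
        rows = []
        for elev, band in ((599.9, "low"), (600.0, "mid"), (1199.9, "mid"),
                           (1200.0, "high")):
            rows.append(
                pd.concat(
                    [
                        make_records([42.0] * 2, elevation=elev, shocked="no"),
                        make_records([42.5] * 2, elevation=elev, shocked="yes"),
                    ]
                )
            )
        out = shock_effect(pd.concat(rows))
        assert set(out["band"]) == {"low", "mid", "high"}

    def test_missing_group_warns_and_omits(self):
        rec = make_records([42.0] * 5, shocked="no")
        with pytest.warns(UserWarning, match="missing"):
            out = shock_effect(rec)
        assert out.empty

    def test_lowland_effect_recovery(self):
        """Neotropical lowland heat-shock effect of -1.61 degC is recovered."""
        from thermotree.synthdata import simulate_shock_experiment

        effects = []
        for rep in range(40):
            rec = simulate_shock_experiment(
                mu_control=42.0, effect=-1.61, sd=1.5, n_per_group=60,
                seed=rep,
            )
            effects.append(shock_effect(rec).iloc[0]["effect_c"])
        se = np.std(effects, ddof=1) / np.sqrt(len(effects))
        assert abs(np.mean(effects) - (-1.61)) < max(3 * se, 0.02)


class TestObserverAnova:
    def test_identical_group_means_give_zero_f(self):
        rec = pd.concat(
            [
                make_records([41.0, 42.0, 43.0], observer=f"obs{k}")
                for k in range(4)
            ]
        )
        fval, df1, df2, p = observer_anova(rec)
        assert fval == pytest.approx(0.0)
        assert (df1, df2) == (3, 8)

    def test_manual_two_group_oracle(self):
        """Hand computation: groups {1,2,3} and {2,3,4} give F = 3/2."""
        rec = pd.concat(
            [
                make_records([1.0, 2.0, 3.0], observer="obsA"),
                make_records([2.0, 3.0, 4.0], observer="obsB"),
            ]
        )
        fval, df1, df2, p = observer_anova(rec)
        assert fval == pytest.approx(1.5)
        assert (df1, df2) == (1, 4)

    def test_single_observer_rejected(self):
        with pytest.raises(ValueError):
            observer_anova(make_records([40.0, 41.0]))

    def test_null_p_values_uniform(self):
        """Permuted observer labels give calibrated (uniform) p-values."""
        from scipy import stats

        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            values = rng.normal(42, 1.5, 40)
            obs = rng.permutation(np.repeat([f"o{k}" for k in range(4)], 10))
            rec = make_records(values)
            rec["observer"] = obs
            ps.append(observer_anova(rec)[3])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
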