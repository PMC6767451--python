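"""Multilevel models, triplicate collapsing, and the published FHC chart."""

import numpy as np
import pandas as pd
import pytest

import centilecharts as cc
from centilecharts.multilevel import (FHC_CHART, marginal_sd_curve,
                                      smooth_sd_curve)


def _triplicate_frame(values, ga=20.0):
    return pd.DataFrame({
        "id": ["A"] * len(values), "visit": [1] * len(values),
        "replicate": list(range(1, len(values) + 1)),
        "ga_weeks": ga, "value": values,
    })


class TestCollapse:
    def test_mean_and_median_of_triplicate(self):
        df = _triplicate_frame([100.0, 102.0, 104.0])
        assert cc.collapse_triplicates(df, "mean")["value"].iloc[0] == 102.0
        assert cc.collapse_triplicates(df, "median")["value"].iloc[0] == 102.0

    def test_random_selects_one_replicate_reproducibly(self):
        df = _triplicate_frame([100.0, 102.0, 104.0])
        a = cc.collapse_triplicates(df, "random", seed=5)["value"].iloc[0]
        b = cc.collapse_triplicates(df, "random", seed=5)["value"].iloc[0]
        assert a == b and a in (100.0, 102.0, 104.0)

    def test_random_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            cc.collapse_triplicates(_triplicate_frame([1.0, 2.0, 3.0]), "random")

    def test_missing_replicates_are_ignored(self):
        df = _triplicate_frame([100.0, np.nan, 104.0])
        assert cc.collapse_triplicates(df, "mean")["value"].iloc[0] == 102.0

    def test_row_counts_visits_times_three_minus_missing(self, small_fetal):
        records, _, _ = small_fetal
        n_visits = records.groupby(["id", "visit"]).ngroups
        n_missing = int(records["value"].isna().sum())
        assert len(records) == n_visits * 3
        assert len(records.dropna(subset=["value"])) == n_visits * 3 - n_missing
        collapsed = cc.collapse_triplicates(records, "mean")
        assert len(collapsed) == n_visits


class TestFitting:
    def test_ri2_recovers_intercept_and_residual_variance(self):
        cfg = cc.LongConfig(n_subjects=500, visits_dist={5: 1.0},
                            var_intercept=25.0, var_slope=0.0, cov_int_slope=0.0,
                            var_visit=4.0, triplicate_sd=0.0, seed=7)
        records, _ = cc.gen_fetal(cfg)
        fit = cc.fit_multilevel(records, "ri2")
        assert fit.var_intercept_ == pytest.approx(25.0, rel=0.15)
        assert fit.var_resid_ == pytest.approx(4.0, rel=0.10)

    def test_ris2_pins_superfluous_slope_variance_at_boundary(self):
        cfg = cc.LongConfig(n_subjects=400, visits_dist={5: 1.0},
                            var_intercept=25.0, var_slope=0.0, cov_int_slope=0.0,
                            var_visit=4.0, triplicate_sd=0.0, seed=8)
        records, _ = cc.gen_fetal(cfg)
        fit = cc.fit_multilevel(records, "ris2", center_ga=True)
        assert fit.var_slope_ < 0.02
        assert fit.var_intercept_ == pytest.approx(25.0, rel=0.2)
        assert "var_slope" in fit.boundary_

    def test_identical_subjects_give_zero_variances_and_single_level_fit(self):
        ga = np.linspace(15.0, 40.0, 6)
        curve = FHC_CHART.mean_curve
        rows = []
        for i in range(40):
            for k, t in enumerate(ga, start=1):
                for rep in (1, 2, 3):
                    rows.append({"id": f"S{i}", "visit": k, "replicate": rep,
                                 "ga_weeks": t, "value": float(curve(t))})
        records = pd.DataFrame(rows)
        fit = cc.fit_multilevel(records, "ri2")
        assert fit.var_intercept_ < 1e-4
        assert fit.var_resid_ < 1e-4
        single = cc.fit_fp(ga, curve(ga), powers=(2.0, 2.0))
        np.testing.assert_allclose(fit.fixed_spec_.coefficients,
                                   single.spec_.coefficients, atol=1e-3)

    def test_ris2_nested_in_ri2_by_deviance(self, small_fetal):
        records, _, _ = small_fetal
        dev_ri = cc.fit_multilevel(records, "ri2").deviance_
        dev_ris = cc.fit_multilevel(records, "ris2").deviance_
        assert dev_ris <= dev_ri + 1e-6

    def test_invalid_kind_rejected(self, small_fetal):
        with pytest.raises(ValueError, match="kind"):
            cc.fit_multilevel(small_fetal[0], "ri9")


class TestMarginalSD:
    def test_zero_random_effects_give_constant_sd(self):
        cfg = cc.LongConfig(n_subjects=200, var_intercept=0.0, var_slope=0.0,
                            cov_int_slope=0.0, var_visit=4.0, triplicate_sd=0.0,
                            seed=9)
        records, _ = cc.gen_fetal(cfg)
        fit = cc.fit_multilevel(records, "ri2")
        grid = np.linspace(15, 40, 11)
        np.testing.assert_allclose(fit.sd_curve_(grid), 2.0, rtol=0.07)

    def test_fp3_smoothing_reproduces_exact_fp3_curve(self):
        grid = np.linspace(14.0, 42.0, 60)
        sd_true = FHC_CHART.sd_curve(grid)
        spec = smooth_sd_curve(grid, sd_true, degree=3)
        np.testing.assert_allclose(spec(grid), sd_true, atol=1e-6)

    def test_total_sd_tracks_generating_model(self, small_fetal):
        records, truth, cfg = small_fetal
        fit = cc.fit_multilevel(records, "ris3")
        grid = np.linspace(16, 38, 12)
        sd = marginal_sd_curve(fit, records)(grid)
        np.testing.assert_allclose(sd, cfg.total_sd(grid), rtol=0.15)


class TestPublishedFHC:
    def test_median_at_40_weeks(self):
        # -28.2849 + 1.69267*1600 - 0.397485*1600*ln(40)
        expected = -28.2849 + 1.69267 * 1600 - 0.397485 * 1600 * np.log(40.0)
        assert cc.published_fhc(40.0, 50.0) == pytest.approx(expected, abs=1e-9)
        assert cc.published_fhc(40.0, 50.0) == pytest.approx(333.9, abs=0.1)

    def test_sd_at_40_weeks(self):
        g3, lg = 40.0**3, np.log(40.0)
        expected = 1.98735 + 0.0136772 * g3 - 0.00726264 * g3 * lg \
            + 0.000976253 * g3 * lg**2
        assert FHC_CHART.sd(40.0) == pytest.approx(expected, abs=1e-9)
        assert FHC_CHART.sd(40.0) == pytest.approx(12.9, abs=0.1)

    def test_zscore_inverts_centile(self):
        val = cc.published_fhc(32.0, 50.0)
        assert cc.published_fhc_zscore(32.0, val) == pytest.approx(0.0, abs=1e-12)
        val97 = cc.published_fhc(32.0, 97.0)
        assert cc.published_fhc_zscore(32.0, val97) == pytest.approx(1.8808, abs=1e-3)

    def test_sd_positive_and_centiles_never_cross_on_chart_range(self):
        grid = np.linspace(14.0, 42.0, 281)
        assert np.all(FHC_CHART.sd(grid) > 0)
        cents = np.column_stack([cc.published_fhc(grid, c)
                                 for c in (3, 10, 50, 90, 97)])
        assert np.all(np.diff(cents, axis=1) > 0)

    def test_centile_validation(self):
        with pytest.raises(ValueError):
            cc.published_fhc(40.0, 0.0)
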