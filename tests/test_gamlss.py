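"""Penalized-likelihood centile models, GAIC, and stepwise class selection."""

import numpy as np
import pytest

import centilecharts as cc
from centilecharts.gamlss import (CentileModel, ConvergenceError, CurveSpec,
                                  FitReport, const, fp, gaic, ps,
                                  stepwise_class_selection)


class TestGAIC:
    def test_aic_special_case(self):
        assert gaic(100.0, 5.0, 2.0) == 110.0

    def test_zero_penalty_returns_deviance(self):
        assert gaic(123.4, 7.0, 0.0) == 123.4

    def test_bic_definition(self):
        # k = ln n with n = e^10 adds exactly 10 per df
        assert gaic(50.0, 1.0, 10.0) == 60.0

    def test_report_reconciles_aic_bic_with_gaic(self):
        rep = FitReport(global_deviance=200.0, df_total=4.5, n_obs=1000,
                        coverage_3rd=3.0, coverage_97th=3.0)
        assert rep.aic == rep.gaic(2.0)
        assert rep.bic == rep.gaic(np.log(1000))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            gaic(100.0, -1.0, 2.0)


class TestCurveSpecs:
    def test_helpers(self):
        assert fp(0, 2).powers == (0.0, 2.0)
        assert ps(3.6).edf == 3.6
        assert const().kind == "constant"

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CurveSpec("fp")
        with pytest.raises(ValueError):
            CurveSpec("pspline", edf=1.5)  # pspline needs edf >= 2
        with pytest.raises(ValueError):
            CurveSpec("wiggly")

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="no parameter"):
            CentileModel(family="NO", curves={"tau": const()}).fit(
                np.linspace(1, 2, 50), np.ones(50))


@pytest.fixture(scope="module")
def fit(bccg_data):
    ga, y, _ = bccg_data
    return cc.fit_centile_model(
        ga, y, family="BCCG",
        curves={"mu": ps(3.0), "sigma": const(), "nu": const()})


class TestBCCGRecovery:
    def test_parameter_curves_recovered(self, fit, bccg_data):
        ga, _, (mu_true, s_true, l_true) = bccg_data
        grid = np.linspace(15, 41, 14)
        np.testing.assert_allclose(fit.curves_["mu"](grid),
                                   100.0 + 5.0 * grid, rtol=0.01)
        assert fit.curves_["sigma"](28.0)[0] == pytest.approx(s_true, rel=0.07)
        assert fit.curves_["nu"](28.0)[0] == pytest.approx(l_true, abs=0.35)

    def test_zscores_standard_normal(self, fit, bccg_data):
        ga, y, _ = bccg_data
        z = fit.zscore(ga, y)
        assert np.mean(z) == pytest.approx(0.0, abs=0.05)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=0.03)

    def test_training_coverage_near_nominal(self, fit):
        assert fit.report_.coverage_3rd == pytest.approx(3.0, abs=0.7)
        assert fit.report_.coverage_97th == pytest.approx(3.0, abs=0.7)

    def test_centiles_do_not_cross(self, fit):
        grid = np.linspace(15, 41, 50)
        vals = np.column_stack([fit.centile(grid, c)
                                for c in (1, 3, 10, 50, 90, 97, 99)])
        assert np.all(np.diff(vals, axis=1) > 0)


def test_normal_fp_fit_agrees_with_meansd_mean():
    """With near-noiseless data the NO-family mu curve and the FP mean-SD
    mean coincide (both are least-squares solutions of the same curve)."""
    rng = np.random.default_rng(31)
    ga = np.linspace(33.0, 42.0, 400)
    y = 10.0 + 2.0 * ga + rng.normal(0, 1e-6, ga.size)
    msd = cc.fit_mean_sd(ga, y)
    gm = cc.fit_centile_model(ga, y, family="NO",
                              curves={"mu": fp(1.0), "sigma": const()})
    grid = np.linspace(34, 41, 15)
    np.testing.assert_allclose(gm.curves_["mu"](grid), msd.mean(grid), atol=1e-3)


def test_edf_two_pspline_is_straight_line():
    rng = np.random.default_rng(32)
    ga = rng.uniform(14, 42, 2000)
    y = rng.normal(10.0 + 2.0 * ga, 1.0)
    fit = cc.fit_centile_model(ga, y, family="NO",
                               curves={"mu": ps(2.0), "sigma": const()})
    grid = np.linspace(ga.min(), ga.max(), 100)
    mu = fit.curves_["mu"](grid)
    curvature = np.diff(mu, 2) / (grid[1] - grid[0]) ** 2
    assert np.max(np.abs(curvature)) < 1e-6
    assert fit.curves_["mu"].edf == pytest.approx(2.0, abs=0.01)


def test_added_edf_never_increases_deviance(bccg_data):
    ga, y, _ = bccg_data
    devs = []
    for edf in (2.0, 4.0, 6.0):
        fit = cc.fit_centile_model(
            ga, y, family="BCCG",
            curves={"mu": ps(edf), "sigma": const(), "nu": const()})
        devs.append(fit.global_deviance_)
    assert devs[1] <= devs[0] + 1e-3
    assert devs[2] <= devs[1] + 1e-3


def test_fractional_edf_honoured(bccg_data):
    ga, y, _ = bccg_data
    fit = cc.fit_centile_model(
        ga, y, family="BCCG",
        curves={"mu": ps(3.6), "sigma": const(), "nu": const()})
    assert fit.curves_["mu"].edf == pytest.approx(3.6, abs=0.02)
    assert fit.report_.df_total == pytest.approx(3.6 + 1 + 1, abs=0.02)


def test_non_convergence_raises_with_trace(bccg_data):
    ga, y, _ = bccg_data
    with pytest.raises(ConvergenceError) as exc:
        cc.fit_centile_model(ga[:500], y[:500], family="BCCG",
                             curves={"mu": ps(3.0)}, tol=0.0, max_cycles=2)
    assert len(exc.value.deviance_trace) >= 1


class TestStepwiseSelection:
    def test_equal_fits_keep_simplest_class(self):
        rng = np.random.default_rng(41)
        ga = rng.uniform(33, 42, 800)
        y = rng.normal(1000.0 + 60.0 * ga, 50.0)
        # the same candidate in two classes ties on deviance: no promotion
        cand = ("NO", {"mu": fp(1.0), "sigma": const()})
        table, chosen = stepwise_class_selection(ga, y, {2: [cand], 3: [cand]})
        assert chosen.family == "NO"
        assert min(r["class"] for r in table) == 2
        assert table[0]["gaic"] <= table[-1]["gaic"]

    def test_skewed_truth_promotes_three_parameter_class(self):
        rng = np.random.default_rng(42)
        ga = rng.uniform(14, 42, 4000)
        y = cc.family_quantile("BCCG", (100 + 5 * ga, 0.15, -2.0),
                               rng.uniform(1e-12, 1 - 1e-12, 4000))
        table, chosen = stepwise_class_selection(ga, y, {
            2: [("NO", {"mu": fp(1.0), "sigma": const()})],
            3: [("BCCG", {"mu": fp(1.0), "sigma": const(), "nu": const()})],
        })
        assert chosen.family == "BCCG"

    def test_normal_truth_retains_normal_model(self):
        rng = np.random.default_rng(43)
        ga = rng.uniform(14, 42, 4000)
        y = rng.normal(100 + 5 * ga, 10.0)
        table, chosen = stepwise_class_selection(ga, y, {
            2: [("NO", {"mu": fp(1.0), "sigma": const()})],
            4: [("BCT", {"mu": fp(1.0), "sigma": const(), "nu": const(),
                         "tau": const()})],
        }, k=2.0)
        assert chosen.family == "NO"

    def test_empty_class_skipped(self):
        rng = np.random.default_rng(44)
        ga = rng.uniform(14, 42, 500)
        y = rng.normal(100 + 5 * ga, 10.0)
        table, chosen = stepwise_class_selection(ga, y, {
            2: [("NO", {"mu": fp(1.0), "sigma": const()})], 3: []})
        assert chosen.family == "NO"
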