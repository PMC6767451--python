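"""Distribution families and the closed-form LMS equations."""

import numpy as np
import pytest
from scipy import stats

import centilecharts as cc
from centilecharts.distributions import LMSTriple, ParamVector, validate_params

CASES = [
    ("NO", (5.0, 2.0)),
    ("PE", (5.0, 2.0, 1.5)),
    ("PE", (5.0, 2.0, 3.0)),
    ("BCCG", (100.0, 0.1, 0.5)),
    ("BCCG", (100.0, 0.1, -1.0)),
    ("BCT", (100.0, 0.1, 0.5, 8.0)),
    ("BCPE", (100.0, 0.1, 0.5, 1.7)),
    ("SEP3", (5.0, 2.0, 1.5, 2.5)),
    ("ST3", (5.0, 2.0, 1.5, 8.0)),
]


@pytest.mark.parametrize("family, params", CASES)
class TestFamilyConsistency:
    def test_pdf_integrates_to_one(self, family, params):
        lo = cc.family_quantile(family, params, 1e-7)
        hi = cc.family_quantile(family, params, 1 - 1e-7)
        grid = np.linspace(lo, hi, 20001)
        total = np.trapezoid(cc.family_pdf(family, params, grid), grid)
        assert total == pytest.approx(1.0, abs=2e-4)

    def test_cdf_monotone_and_quantile_inverse(self, family, params):
        p = np.linspace(1e-6, 1 - 1e-6, 501)
        q = cc.family_quantile(family, params, p)
        assert np.all(np.diff(q) > 0)
        np.testing.assert_allclose(cc.family_cdf(family, params, q), p,
                                   atol=1e-8)

    def test_pdf_is_cdf_derivative(self, family, params):
        q = cc.family_quantile(family, params, np.linspace(0.05, 0.95, 41))
        h = 1e-5 * np.maximum(np.abs(q), 1.0)
        num = (cc.family_cdf(family, params, q + h)
               - cc.family_cdf(family, params, q - h)) / (2 * h)
        np.testing.assert_allclose(cc.family_pdf(family, params, q), num,
                                   rtol=1e-4)

    def test_random_seeded_and_reproducible(self, family, params):
        a = cc.family_random(family, params, 100, seed=9)
        b = cc.family_random(family, params, 100, seed=9)
        c = cc.family_random(family, params, 100, seed=10)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestSpecialCases:
    def test_no_cdf_at_mean_is_half(self):
        assert cc.family_cdf("NO", (3.0, 1.5), 3.0) == pytest.approx(0.5)

    def test_pe_tau2_is_normal(self):
        y = np.linspace(-4, 8, 50)
        np.testing.assert_allclose(cc.family_pdf("PE", (2.0, 1.5, 2.0), y),
                                   stats.norm.pdf(y, 2.0, 1.5), rtol=1e-10)

    def test_bccg_nu1_quantile_is_linear(self):
        M, S = 100.0, 0.05
        p = np.array([0.1, 0.25, 0.5, 0.75, 0.9])
        z = stats.norm.ppf(p)
        # for nu=1 the transform is linear, so quantiles are M(1 + S z)
        # up to the (negligible at S=0.05) positivity truncation
        np.testing.assert_allclose(cc.family_quantile("BCCG", (M, S, 1.0), p),
                                   M * (1 + S * z), rtol=1e-8)

    def test_bct_approaches_bccg_for_large_tau(self):
        p = np.linspace(0.01, 0.99, 25)
        q_t = cc.family_quantile("BCT", (100.0, 0.1, 0.5, 1e6), p)
        q_g = cc.family_quantile("BCCG", (100.0, 0.1, 0.5), p)
        np.testing.assert_allclose(q_t, q_g, rtol=1e-3)

    def test_bcpe_tau2_matches_bccg(self):
        p = np.linspace(0.01, 0.99, 25)
        np.testing.assert_allclose(
            cc.family_quantile("BCPE", (100.0, 0.1, 0.5, 2.0), p),
            cc.family_quantile("BCCG", (100.0, 0.1, 0.5), p), rtol=1e-8)

    def test_sep3_reduces_to_normal(self):
        y = np.linspace(-5, 9, 60)
        np.testing.assert_allclose(cc.family_pdf("SEP3", (2.0, 1.5, 1.0, 2.0), y),
                                   stats.norm.pdf(y, 2.0, 1.5), rtol=1e-10)

    def test_st3_approaches_normal(self):
        y = np.linspace(-3, 7, 60)
        np.testing.assert_allclose(cc.family_pdf("ST3", (2.0, 1.5, 1.0, 1e6), y),
                                   stats.norm.pdf(y, 2.0, 1.5), rtol=1e-3)

    def test_bccg_sample_sds_close_to_standard_normal(self):
        triple = LMSTriple(L=0.5, M=100.0, S=0.08)
        y = cc.family_random("BCCG", (triple.M, triple.S, triple.L), 4000, seed=3)
        z = np.array([cc.lms_sds(v, triple) for v in y])
        assert stats.kstest(z, "norm").pvalue > 0.01


class TestValidation:
    @pytest.mark.parametrize("family, params", [
        ("NO", (0.0, -1.0)),         # sigma <= 0
        ("BCCG", (-5.0, 0.1, 1.0)),  # mu <= 0
        ("BCT", (100.0, 0.1, 0.5, -2.0)),  # tau <= 0
        ("SEP3", (0.0, 1.0, -1.0, 2.0)),   # nu <= 0
    ])
    def test_invalid_params_rejected(self, family, params):
        with pytest.raises(ValueError):
            validate_params(family, *params)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            cc.family_cdf("XYZ", (0, 1), 0.0)

    def test_quantile_probability_domain(self):
        with pytest.raises(ValueError):
            cc.family_quantile("NO", (0.0, 1.0), 1.2)

    def test_param_vector_counts(self):
        pv = ParamVector("BCCG", mu=100.0, sigma=0.1, nu=1.0)
        assert pv.as_tuple() == (100.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            ParamVector("BCT", mu=100.0, sigma=0.1, nu=1.0)  # tau missing


class TestLMSEquations:
    def test_median_centile_is_m(self):
        assert cc.lms_centile(LMSTriple(1.0, 100.0, 0.1), 50) == pytest.approx(100.0)

    def test_lognormal_branch_97th(self):
        # M exp(S z_0.97) with z = 1.8808
        val = cc.lms_centile(LMSTriple(0.0, 100.0, 0.1), 97)
        assert val == pytest.approx(100.0 * np.exp(0.1 * stats.norm.ppf(0.97)),
                                    rel=1e-12)
        assert val == pytest.approx(120.7, abs=0.05)

    def test_branch_continuity_at_l_zero(self):
        for c in (3, 25, 50, 75, 97):
            a = cc.lms_centile(LMSTriple(1e-12, 100.0, 0.1), c)
            b = cc.lms_centile(LMSTriple(0.0, 100.0, 0.1), c)
            assert a == pytest.approx(b, rel=1e-6)

    @pytest.mark.parametrize("L", [-0.7, 0.0, 0.5, 1.0, 2.0])
    def test_sds_inverts_centile(self, L):
        triple = LMSTriple(L, 50.0, 0.12)
        for c in (3, 10, 50, 90, 97):
            z = stats.norm.ppf(c / 100)
            y = cc.lms_centile(triple, c)
            assert cc.lms_sds(y, triple) == pytest.approx(z, abs=1e-10)

    def test_sds_at_median_is_zero(self):
        for L in (-1.0, 0.0, 2.0):
            assert cc.lms_sds(80.0, LMSTriple(L, 80.0, 0.2)) == pytest.approx(0.0)

    def test_lognormal_one_sd(self):
        t = LMSTriple(0.0, 100.0, 0.1)
        assert cc.lms_sds(100.0 * np.exp(0.1), t) == pytest.approx(1.0)

    def test_out_of_support_centile_rejected(self):
        with pytest.raises(ValueError, match="support|centile"):
            cc.lms_centile(LMSTriple(3.0, 100.0, 0.5), 3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cc.lms_sds(-1.0, LMSTriple(1.0, 100.0, 0.1))
        with pytest.raises(ValueError):
            cc.lms_centile(LMSTriple(1.0, 100.0, 0.1), 0)
        with pytest.raises(ValueError):
            LMSTriple(1.0, -5.0, 0.1)
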