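"""Core distribution kernels: identities, stability, inversion, sampling."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import kstest

from tlechen import (
    SaturationError,
    TlecParams,
    chen_cdf,
    chen_pdf,
    ec_cdf,
    ec_pdf,
    tl_cdf,
    tl_pdf,
    tlc_cdf,
    tlc_pdf,
    tlec_cdf,
    tlec_hazard,
    tlec_logpdf,
    tlec_pdf,
    tlec_quantile,
    tlec_rvs,
    tlec_survival,
)

from conftest import BASE, CASES


class TestParams:
    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_rejects_nonpositive_or_nonfinite(self, bad):
        with pytest.raises(ValueError):
            TlecParams(bad, 0.9, 0.5, 0.3)
        with pytest.raises(ValueError):
            TlecParams(0.6, 0.9, bad, 0.3)

    def test_array_roundtrip(self):
        p = TlecParams(0.6, 0.9, 0.5, 0.3)
        assert TlecParams.from_array(p.as_array()) == p


class TestCdf:
    def test_zero_at_origin_and_monotone(self, base_params):
        assert tlec_cdf(0.0, base_params) == 0.0
        x = np.logspace(-8, 1, 200)
        F = tlec_cdf(x, base_params)
        assert np.all(np.diff(F) >= 0)
        assert np.all((F >= 0) & (F <= 1))

    def test_cdf_equals_integral_of_pdf(self, base_params):
        # adaptive-quadrature oracle on (0, 1]
        val, err = quad(lambda u: tlec_pdf(u, base_params), 0.0, 1.0,
                        epsabs=1e-12, limit=200)
        assert tlec_cdf(1.0, base_params) == pytest.approx(val, abs=1e-8)

    def test_negative_x_rejected(self, base_params):
        with pytest.raises(ValueError):
            tlec_cdf(-0.1, base_params)

    def test_decreasing_in_alpha(self):
        # the base of the outer power lies in (0,1), so F falls as alpha grows
        x = np.array([1e-4, 1e-2, 0.5, 2.0])
        alphas = [0.3, 0.6, 1.0, 2.0, 4.0]
        prev = None
        for a in alphas:
            F = tlec_cdf(x, TlecParams(a, 0.9, 0.5, 0.3))
            if prev is not None:
                assert np.all(F < prev)
            prev = F

    def test_generator_identity(self, random_param_draws):
        # composing the Topp-Leone CDF with the exponentiated-Chen CDF must
        # reproduce the four-parameter CDF exactly
        rng = np.random.default_rng(42)
        for p in random_param_draws:
            x = rng.uniform(0.01, 3.0, size=10)
            v = ec_cdf(x, p.lam, p.beta, p.b)
            assert tlec_cdf(x, p) == pytest.approx(tl_cdf(v, p.alpha), abs=1e-12)

    def test_saturated_region_is_exact(self, base_params):
        x = 1e12  # x**beta far beyond exp overflow
        assert tlec_cdf(x, base_params) == 1.0
        assert tlec_survival(x, base_params) == 0.0
        assert tlec_logpdf(x, base_params) == -np.inf


class TestLogPdf:
    def test_matches_topp_leone_of_chen_at_alpha_b_one(self):
        # alpha=1, b=1 zeroes both bracketed exponents: density reduces to
        # 2 * f_C * (1 - F_C)
        lam, beta = 0.9, 0.5
        p = TlecParams(1.0, lam, beta, 1.0)
        x = np.linspace(0.05, 4.0, 50)
        expected = np.log(2.0) + np.log(chen_pdf(x, lam, beta)) + np.log1p(
            -chen_cdf(x, lam, beta)
        )
        assert tlec_logpdf(x, p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("case", [1, 2, 3])
    def test_density_normalises(self, case):
        # mass spans hundreds of decades for small alpha*beta*b, so integrate
        # in u = log x and restore the sub-representable left tail as F(lo)
        p = CASES[case]
        hi = float(tlec_quantile(1.0 - 1e-12, p))
        lo = max(float(tlec_quantile(1e-12, p)), 1e-300)
        val, _ = quad(
            lambda u: np.exp(u) * tlec_pdf(np.exp(u), p),
            np.log(lo), np.log(hi), epsabs=1e-10, limit=300,
        )
        val += tlec_cdf(lo, p)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_cdf_derivative(self, base_params):
        x, h = 0.7, 1e-6
        deriv = (tlec_cdf(x + h, base_params) - tlec_cdf(x - h, base_params)) / (2 * h)
        assert np.exp(tlec_logpdf(x, base_params)) == pytest.approx(deriv, rel=1e-6)

    def test_nonpositive_x_rejected(self, base_params):
        with pytest.raises(ValueError):
            tlec_logpdf(0.0, base_params)
        with pytest.raises(ValueError):
            tlec_logpdf(-1.0, base_params)


class TestSurvivalHazard:
    def test_complement_identity(self, base_params):
        x = np.logspace(-6, 0.8, 60)
        assert tlec_survival(x, base_params) + tlec_cdf(x, base_params) == pytest.approx(
            np.ones_like(x), abs=1e-12
        )
        assert tlec_survival(0.0, base_params) == 1.0
        sf = tlec_survival(np.sort(x), base_params)
        assert np.all(np.diff(sf) <= 0)

    def test_hazard_is_pdf_over_survival(self, base_params):
        x = np.logspace(-4, 0.5, 40)
        expected = tlec_pdf(x, base_params) / tlec_survival(x, base_params)
        assert tlec_hazard(x, base_params) == pytest.approx(expected, rel=1e-10)

    def test_hazard_increasing_regime(self):
        # all shape parameters above one give an increasing failure rate
        p = CASES[3]
        x = np.linspace(0.05, 1.6, 120)
        h = tlec_hazard(x, p)
        assert np.all(np.diff(h) > 0)

    def test_hazard_saturation_signalled(self, base_params):
        with pytest.raises(SaturationError):
            tlec_hazard(1e12, base_params)

    def test_sub_family_consistency_b1_alpha1(self):
        lam, beta = 0.9, 0.5
        p = TlecParams(1.0, lam, beta, 1.0)
        x = np.linspace(0.1, 3.0, 30)
        fc = chen_pdf(x, lam, beta)
        Fc = chen_cdf(x, lam, beta)
        expected = 2.0 * fc * (1.0 - Fc) / (1.0 - (1.0 - (1.0 - Fc) ** 2))
        assert tlec_hazard(x, p) == pytest.approx(expected, rel=1e-10)


class TestQuantile:
    def test_boundary_and_roundtrip(self, base_params):
        assert tlec_quantile(0.0, base_params) == 0.0
        ps = np.array([1e-6, 0.01, 0.25, 0.5, 0.75, 0.99, 1.0 - 1e-6])
        q = tlec_quantile(ps, base_params)
        assert np.all(np.diff(q) > 0)
        assert tlec_cdf(q, base_params) == pytest.approx(ps, abs=1e-9)

    def test_against_bisection_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = TlecParams(*np.exp(rng.uniform(np.log(0.2), np.log(3.0), 4)))
            prob = rng.uniform(0.01, 0.99)
            x_closed = tlec_quantile(prob, p)
            hi = 1.0
            while tlec_cdf(hi, p) < prob:
                hi *= 2
            x_root = brentq(lambda z: tlec_cdf(z, p) - prob, 0.0, hi, xtol=1e-14)
            assert x_closed == pytest.approx(x_root, rel=1e-8, abs=1e-12)

    def test_domain_errors(self, base_params):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                tlec_quantile(bad, base_params)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        prob=st.floats(1e-5, 1 - 1e-5),
        a=st.floats(0.3, 3.0),
        lam=st.floats(0.3, 3.0),
        beta=st.floats(0.3, 3.0),
        b=st.floats(0.3, 3.0),
    )
    def test_roundtrip_property(self, prob, a, lam, beta, b):
        p = TlecParams(a, lam, beta, b)
        q = tlec_quantile(prob, p)
        assume(q > 0.0)  # true quantile can undercut the smallest double
        assert tlec_cdf(q, p) == pytest.approx(prob, abs=1e-9)


class TestSampling:
    def test_seed_determinism(self, base_params):
        a = tlec_rvs(100, base_params, seed=7)
        b = tlec_rvs(100, base_params, seed=7)
        np.testing.assert_array_equal(a, b)
        c = tlec_rvs(100, base_params, seed=8)
        assert not np.array_equal(a, c)

    def test_kolmogorov_smirnov(self, base_params):
        x = tlec_rvs(10_000, base_params, seed=11)
        stat = kstest(x, lambda v: tlec_cdf(v, base_params)).statistic
        assert stat < 1.63 / np.sqrt(10_000)  # 1% critical value

    def test_invalid_n(self, base_params):
        with pytest.raises(ValueError):
            tlec_rvs(0, base_params, seed=1)


class TestSubModels:
    def test_chen_basics(self):
        lam, beta = 0.9, 0.5
        assert chen_cdf(0.0, lam, beta) == 0.0
        val, _ = quad(lambda u: chen_pdf(u, lam, beta), 0.0, 60.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)
        x, h = 0.8, 1e-6
        deriv = (chen_cdf(x + h, lam, beta) - chen_cdf(x - h, lam, beta)) / (2 * h)
        assert chen_pdf(x, lam, beta) == pytest.approx(deriv, rel=1e-6)

    def test_ec_reduces_to_chen_at_b1(self):
        x = np.linspace(0.0, 5.0, 60)
        assert ec_cdf(x, 0.9, 0.5, 1.0) == pytest.approx(chen_cdf(x, 0.9, 0.5), abs=1e-14)

    def test_ec_normalises_and_inverts(self):
        lam, beta, b = 0.7, 0.6, 1.8
        val, _ = quad(lambda u: ec_pdf(u, lam, beta, b), 0.0, 80.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)
        # numeric inversion oracle for the CDF (no closed quantile used)
        for prob in (0.2, 0.5, 0.9):
            root = brentq(lambda z: ec_cdf(z, lam, beta, b) - prob, 1e-12, 100.0)
            assert ec_cdf(root, lam, beta, b) == pytest.approx(prob, abs=1e-10)

    def test_tlc_is_tlec_with_b1(self):
        a, lam, beta = 0.8, 0.9, 0.5
        p = TlecParams(a, lam, beta, 1.0)
        x = np.linspace(0.01, 4.0, 80)
        assert tlc_cdf(x, a, lam, beta) == pytest.approx(tlec_cdf(x, p), abs=1e-12)
        assert tlc_pdf(x, a, lam, beta) == pytest.approx(tlec_pdf(x, p), rel=1e-12)

    def test_tlc_normalises_and_matches_derivative(self):
        a, lam, beta = 1.3, 0.4, 0.8
        val, _ = quad(lambda u: tlc_pdf(u, a, lam, beta), 0.0, 40.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)
        x, h = 1.1, 1e-6
        deriv = (tlc_cdf(x + h, a, lam, beta) - tlc_cdf(x - h, a, lam, beta)) / (2 * h)
        assert tlc_pdf(x, a, lam, beta) == pytest.approx(deriv, rel=1e-6)

    def test_topp_leone_on_unit_interval(self):
        assert tl_cdf(1.0, 2.3) == pytest.approx(1.0)
        assert tl_cdf(0.5, 1.0) == pytest.approx(0.75)  # 0.5 * 1.5
        val, _ = quad(lambda v: tl_pdf(v, 1.7), 0.0, 1.0)
        assert val == pytest.approx(1.0, abs=1e-8)
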