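"""Unit and property tests for the ExG / AL / ALG distribution machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats as sps

import algsst as a
from algsst import ALGParams, ALParams, ExGParams, ParameterError

from conftest import random_alg_params, random_exg_params
from _oracles import alg_cdf_quadrature, alg_pdf_quadrature

param_scale = st.floats(min_value=15.0, max_value=300.0)


# ---------------------------------------------------------------------------
# Parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    lambda: ExGParams(0, -1, 10),
    lambda: ExGParams(0, 10, 0),
    lambda: ExGParams(float("nan"), 10, 10),
    lambda: ALParams(-1, 10),
    lambda: ALParams(5, 0),
    lambda: ALGParams(-1, 10, 0, 10),
    lambda: ALGParams(5, 10, 0, 0),
])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ParameterError):
        bad()


def test_al_alpha1_zero_is_exponential():
    p = ALParams(0.0, 50.0)
    assert a.al_pdf(-1.0, p) == 0.0
    assert a.al_pdf(0.0, p) == pytest.approx(1 / 50.0)
    assert a.al_cdf(100.0, p) == pytest.approx(1 - math.exp(-2.0))


# ---------------------------------------------------------------------------
# Densities against frozen oracle values and independent implementations
# ---------------------------------------------------------------------------

def test_exg_pdf_frozen_oracle_value():
    # quadrature convolution of N(0,1) and Exp(1) at t = 0
    assert a.exg_pdf(0.0, ExGParams(0, 1, 1)) == pytest.approx(
        0.26157829186512344, abs=1e-12)


def test_exg_pdf_cdf_match_scipy_exponnorm():
    rng = np.random.default_rng(7)
    for p in random_exg_params(rng, 10):
        ref = sps.exponnorm(K=p.tau / p.sigma, loc=p.mu, scale=p.sigma)
        t = np.linspace(p.mu - 6 * p.sigma, p.mu + 6 * p.sigma + 8 * p.tau, 97)
        np.testing.assert_allclose(a.exg_pdf(t, p), ref.pdf(t),
                                   rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(a.exg_cdf(t, p), ref.cdf(t),
                                   rtol=1e-8, atol=1e-10)


def test_exg_pdf_gaussian_limit_small_tau():
    p = ExGParams(0.0, 1.0, 1e-4)
    t = np.linspace(-5, 5, 201)
    dev = np.abs(a.exg_pdf(t, p) - sps.norm.pdf(t))
    assert dev.max() < 1e-3  # tau shifts the density by ~tau
    # sharper check against the tau-shifted Gaussian
    dev2 = np.abs(a.exg_pdf(t, p) - sps.norm.pdf(t - 1e-4))
    assert dev2.max() < 1e-6


def test_al_pdf_values_and_normalisation():
    assert a.al_pdf(0.0, ALParams(1, 1)) == pytest.approx(0.5)
    assert a.al_pdf(100.0, ALParams(104.2, 142.4)) == pytest.approx(
        0.0020092077642608025, rel=1e-12)
    val, _ = integrate.quad(lambda t: a.al_pdf(t, ALParams(104.2, 142.4)),
                            -4000, 6000, points=[0.0], limit=200)
    assert val == pytest.approx(1.0, abs=1e-9)


def test_alg_pdf_frozen_oracle_values():
    assert a.alg_pdf(0.0, ALGParams(1, 1, 0, 1)) == pytest.approx(
        0.26157829186512344, abs=1e-12)
    assert a.alg_cdf(1.0, ALGParams(1, 1, 0, 1)) == pytest.approx(
        0.7406915899908364, abs=1e-12)


def test_alg_pdf_cdf_match_quadrature_convolution():
    rng = np.random.default_rng(11)
    for p in random_alg_params(rng, 8):
        s = a.alg_stats(p)
        for t in np.linspace(s.mean - 4 * s.sd, s.mean + 4 * s.sd, 9):
            assert a.alg_pdf(t, p) == pytest.approx(
                alg_pdf_quadrature(float(t), p), abs=1e-10)
            assert a.alg_cdf(t, p) == pytest.approx(
                alg_cdf_quadrature(float(t), p), abs=1e-10)


def test_alg_degenerates_to_exg_at_alpha1_zero():
    exg = ExGParams(53.9, 172.6, 142.4)
    p0 = ALGParams(0.0, 142.4, 53.9, 172.6)
    t = np.linspace(-600, 1400, 301)
    np.testing.assert_allclose(a.alg_pdf(t, p0), a.exg_pdf(t, exg),
                               rtol=0, atol=1e-14)
    # and continuously as alpha1 -> 0+
    p_eps = ALGParams(1e-7, 142.4, 53.9, 172.6)
    assert np.max(np.abs(a.alg_pdf(t, p_eps) - a.exg_pdf(t, exg))) < 1e-10


@settings(max_examples=20, deadline=None, derandomize=True)
@given(a1=param_scale, a2=param_scale, sigma=param_scale,
       mu=st.floats(min_value=-200, max_value=200))
def test_alg_pdf_normalises_to_one(a1, a2, mu, sigma):
    p = ALGParams(a1, a2, mu, sigma)
    s = a.alg_stats(p)
    val, _ = integrate.quad(lambda t: a.alg_pdf(t, p),
                            s.mean - 30 * s.sd, s.mean + 40 * s.sd,
                            points=[s.mean], limit=300)
    assert val == pytest.approx(1.0, abs=1e-8)


def test_alg_cdf_limits_monotone_and_derivative():
    p = ALGParams(104.2, 142.4, 53.9, 172.6)
    s = a.alg_stats(p)
    t = np.linspace(s.mean - 8 * s.sd, s.mean + 8 * s.sd, 400)
    F = a.alg_cdf(t, p)
    assert np.all(np.diff(F) >= 0)
    assert a.alg_cdf(s.mean - 40 * s.sd, p) == pytest.approx(0.0, abs=1e-12)
    assert a.alg_cdf(s.mean + 60 * s.sd, p) == pytest.approx(1.0, abs=1e-12)
    h = 1e-3
    num = (a.alg_cdf(t + h, p) - a.alg_cdf(t - h, p)) / (2 * h)
    np.testing.assert_allclose(num, a.alg_pdf(t, p), atol=1e-6)


def test_alg_cdf_symmetric_case_half_at_mu():
    assert a.alg_cdf(10.0, ALGParams(80, 80, 10, 40)) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# MGFs and cumulants
# ---------------------------------------------------------------------------

def test_exg_mgf_closed_form_and_domain():
    p = ExGParams(0, 1, 1)
    assert a.exg_mgf(0.0, p) == pytest.approx(1.0)
    assert a.exg_mgf(0.5, p) == pytest.approx(2 * math.exp(0.125))
    with pytest.raises(ParameterError):
        a.exg_mgf(1.0, p)


def test_exg_mgf_against_monte_carlo():
    p = ExGParams(500, 100, 150)
    t = 0.002
    draws = a.sample("ExG", p, 10 ** 6, seed=5)
    vals = np.exp(t * draws)
    se = vals.std(ddof=1) / math.sqrt(len(vals))
    assert abs(a.exg_mgf(t, p) - vals.mean()) < 3 * se


def test_alg_mgf_is_product_of_component_mgfs(theta_a, theta_b):
    # MGF of ExG_B times the reflected MGF of ExG_A equals the ALG MGF
    p = a.alg_from_components(theta_a, theta_b)
    for t in (-0.005, -0.001, 0.0, 0.001, 0.004):
        expected = a.exg_mgf(t, theta_b) * a.exg_mgf(-t, theta_a)
        assert a.alg_mgf(t, p) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("n", range(1, 7))
def test_alg_cumulant_additivity(n, alg_group):
    p = alg_group
    al = ALParams(p.alpha1, p.alpha2)
    gauss = p.mu if n == 1 else (p.sigma ** 2 if n == 2 else 0.0)
    assert a.alg_cumulant(n, p) == pytest.approx(
        a.al_cumulant(n, al) + gauss, rel=1e-12)


def test_alg_cumulant_values(alg_group):
    assert a.alg_cumulant(1, alg_group) == pytest.approx(92.1)
    assert a.alg_cumulant(3, ALGParams(70, 70, 12, 30)) == 0.0
    assert a.alg_cumulant(4, ALGParams(1, 2, 0, 1)) == pytest.approx(102.0)
    with pytest.raises(ParameterError):
        a.alg_cumulant(0, alg_group)


# ---------------------------------------------------------------------------
# Moments, shape statistics and classification
# ---------------------------------------------------------------------------

def test_exg_stats_table_means(theta_a, theta_b):
    assert a.exg_stats(theta_a).mean == pytest.approx(583.0)
    assert a.exg_stats(theta_b).mean == pytest.approx(675.1, abs=0.1)


def test_exg_stats_gaussian_limit():
    s = a.exg_stats(ExGParams(0, 100, 1e-3))
    assert abs(s.skewness) < 1e-9
    assert s.full_kurtosis == pytest.approx(3.0)


def test_al_stats_closed_forms():
    s = a.al_stats(ALParams(104.2, 142.4))
    assert s.mean == pytest.approx(38.2)
    sym = a.al_stats(ALParams(90, 90))
    assert sym.skewness == 0.0
    assert sym.skew_class == "symmetric"
    # full kurtosis of the symmetric Laplace is 6
    assert sym.full_kurtosis == pytest.approx(6.0)


def test_al_variance_against_monte_carlo():
    p = ALParams(104.2, 142.4)
    draws = a.sample("AL", p, 10 ** 6, seed=9)
    v = draws.var(ddof=1)
    se = np.sqrt((np.mean((draws - draws.mean()) ** 4) - v ** 2) / len(draws))
    assert abs(a.al_stats(p).variance - v) < 3 * se


def test_alg_stats_group_values(alg_group):
    s = a.alg_stats(alg_group)
    assert s.mean == pytest.approx(92.1)
    assert s.variance == pytest.approx(104.2 ** 2 + 142.4 ** 2 + 172.6 ** 2)
    assert s.full_kurtosis == pytest.approx(s.excess_kurtosis + 3.0)
    assert s.skew_class == "positive"
    assert s.kurtosis_class == "platykurtic"


def test_alg_stats_symmetric():
    s = a.alg_stats(ALGParams(80, 80, 0, 50))
    assert s.skewness == 0.0
    assert s.skew_class == "symmetric"


def test_classify_shape_rules():
    assert a.classify_shape(ALGParams(50, 150, 0, 40))[0] == "positive"
    assert a.classify_shape(ALGParams(150, 50, 0, 40))[0] == "negative"
    # equal tails: lhs of the kurtosis rule is exactly 0 < sigma^2
    assert a.classify_shape(ALGParams(90, 90, 0, 40)) == ("symmetric",
                                                          "platykurtic")
    # heavy unequal tails with a tiny Gaussian part are leptokurtic
    assert a.classify_shape(ALGParams(20, 300, 0, 15))[1] == "leptokurtic"


def test_alg_moments_against_monte_carlo():
    from _oracles import batched_moment_estimates
    p = ALGParams(80, 150, 50, 120)
    draws = a.sample("ALG", p, 10 ** 6, seed=13)
    est, se = batched_moment_estimates(draws)
    s = a.alg_stats(p)
    target = np.array([s.mean, s.variance, s.skewness, s.excess_kurtosis])
    assert np.all(np.abs(target - est) < 3 * se)


# ---------------------------------------------------------------------------
# Hazard functions
# ---------------------------------------------------------------------------

def test_alg_hazard_reaches_exponential_asymptote(alg_group):
    h = a.hazard(3000.0, "ALG", alg_group)
    assert h == pytest.approx(1 / 142.4, rel=0.01)
    # far beyond survival underflow: still the asymptote, never NaN
    h_far = a.hazard(1e7, "ALG", alg_group)
    assert np.isfinite(h_far) and h_far == pytest.approx(1 / 142.4, rel=1e-6)


def test_al_hazard_constant_on_positive_axis():
    p = ALParams(0.0, 150.0)
    t = np.linspace(0, 2000, 50)
    np.testing.assert_allclose(a.hazard(t, "AL", p), 1 / 150.0)


def test_hazard_monotone_on_random_parameters():
    rng = np.random.default_rng(17)
    for p in random_alg_params(rng, 10):
        s = a.alg_stats(p)
        t = np.linspace(s.mean - 6 * s.sd, s.mean + 8 * s.sd, 800)
        h = a.hazard(t, "ALG", p)
        assert np.all(np.diff(h) >= -1e-9)
    for p in random_exg_params(rng, 10):
        s = a.exg_stats(p)
        t = np.linspace(s.mean - 6 * s.sd, s.mean + 8 * s.sd, 800)
        h = a.hazard(t, "ExG", p)
        assert np.all(np.diff(h) >= -1e-9)


def test_alg_log_density_tail_slope():
    rng = np.random.default_rng(23)
    for p in random_alg_params(rng, 10, tail_safe=True):
        s = a.alg_stats(p)
        t = np.linspace(s.mean + 6 * s.sd, s.mean + 10 * s.sd, 50)
        slope = np.polyfit(t, a.alg_logpdf(t, p), 1)[0]
        assert slope == pytest.approx(-1 / p.alpha2, rel=0.01)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def test_sample_mean_matches_closed_form():
    draws = a.sample("ExG", ExGParams(500, 100, 150), 10 ** 6, seed=3)
    se = draws.std(ddof=1) / math.sqrt(len(draws))
    assert abs(draws.mean() - 650.0) < 3 * se


def test_sample_single_draw_and_errors(alg_group):
    x = a.sample("ALG", alg_group, 1, seed=1)
    assert x.shape == (1,) and np.isfinite(x[0])
    with pytest.raises(ParameterError):
        a.sample("ALG", alg_group, 0)
    with pytest.raises(ParameterError):
        a.sample("XYZ", alg_group, 10)


def test_sample_reproducible(alg_group):
    x = a.sample("ALG", alg_group, 100, seed=42)
    y = a.sample("ALG", alg_group, 100, seed=42)
    np.testing.assert_array_equal(x, y)


def test_alg_draws_distributed_as_component_difference(theta_a, theta_b):
    # ExG_B - ExG_A differences vs the plug-in ALG law
    n = 10 ** 5
    rng = np.random.default_rng(29)
    diffs = (a.sample("ExG", theta_b, n, seed=rng) -
             a.sample("ExG", theta_a, n, seed=rng))
    p = a.alg_from_components(theta_a, theta_b)
    res = sps.kstest(diffs, lambda t: a.alg_cdf(t, p))
    assert res.pvalue > 0.01


# ---------------------------------------------------------------------------
# Quantiles, median, mode
# ---------------------------------------------------------------------------

def test_quantile_cdf_round_trip(alg_group):
    for q in np.arange(0.01, 1.0, 0.07):
        t = a.alg_quantile(float(q), alg_group)
        assert a.alg_cdf(t, alg_group) == pytest.approx(q, abs=1e-8)


def test_symmetric_median_and_mode_at_mu():
    p = ALGParams(60, 60, 25.0, 40)
    assert a.alg_median(p) == pytest.approx(25.0, abs=1e-6)
    assert a.alg_mode(p) == pytest.approx(25.0, abs=1e-4)
    assert a.alg_quantile(0.5, ALGParams(1, 1, 0, 1)) == pytest.approx(
        0.0, abs=1e-9)


def test_quantile_domain_errors(alg_group):
    for q in (0.0, 1.0, -0.2, 1.3):
        with pytest.raises(ParameterError):
            a.alg_quantile(q, alg_group)


# ---------------------------------------------------------------------------
# Plug-in construction and non-identifiability
# ---------------------------------------------------------------------------

def test_alg_from_components_group_values(theta_a, theta_b):
    p = a.alg_from_components(theta_a, theta_b)
    assert p.alpha1 == pytest.approx(104.2)
    assert p.alpha2 == pytest.approx(142.4)
    assert p.mu == pytest.approx(54.0)
    assert p.sigma == pytest.approx(math.hypot(109.9, 133.1), rel=1e-12)
    # the per-participant-averaged sigma of the source table (179.2) must
    # NOT equal this group-mean plug-in value
    assert abs(p.sigma - 179.2) > 1.0


def test_components_equivalence_classes(theta_a, theta_b):
    shift = 100.0
    pair_shifted = (
        ExGParams(theta_a.mu + shift, theta_a.sigma, theta_a.tau),
        ExGParams(theta_b.mu + shift, theta_b.sigma, theta_b.tau),
    )
    assert a.components_equivalent((theta_a, theta_b), pair_shifted)
    pair_swapped_sigma = (
        ExGParams(theta_a.mu, theta_b.sigma, theta_a.tau),
        ExGParams(theta_b.mu, theta_a.sigma, theta_b.tau),
    )
    assert a.components_equivalent((theta_a, theta_b), pair_swapped_sigma)
    pair_tau = (
        ExGParams(theta_a.mu, theta_a.sigma, theta_a.tau + 10),
        theta_b,
    )
    assert not a.components_equivalent((theta_a, theta_b), pair_tau)
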