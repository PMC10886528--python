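"""Distribution library: densities, normalisers, moments, and samplers."""

import math

import numpy as np
import pytest
from scipy import stats

from skewfit import (
    DomainError,
    NumericalError,
    ParameterSet,
    cmp_normalizer,
    family_mean,
    get_family,
    log_density,
)
from skewfit.families import FAMILY_NAMES

Y_GRID = np.arange(0, 31)


def test_poisson_logmass_worked_example():
    # P(0; mu=1) = e^{-1}
    assert log_density("poisson", 0, ParameterSet([0.0])) == pytest.approx(-1.0, abs=1e-12)


@pytest.mark.parametrize("mu", [0.5, 2.0, 7.3])
def test_cmp_nu_one_is_poisson(mu):
    p_cmp = ParameterSet([np.log(mu)], 1.0)
    p_poi = ParameterSet([np.log(mu)])
    d = log_density("cmp", Y_GRID, p_cmp) - log_density("poisson", Y_GRID, p_poi)
    assert np.max(np.abs(d)) < 1e-10


@pytest.mark.parametrize("mu", [0.5, 2.0, 7.3])
def test_gp_delta_zero_is_poisson(mu):
    p_gp = ParameterSet([np.log(mu)], 0.0)
    p_poi = ParameterSet([np.log(mu)])
    d = log_density("gp", Y_GRID, p_gp) - log_density("poisson", Y_GRID, p_poi)
    assert np.max(np.abs(d)) < 1e-10


def test_nb_small_alpha_approaches_poisson():
    p_nb = ParameterSet([np.log(2.0)], 1e-8)
    p_poi = ParameterSet([np.log(2.0)])
    d = log_density("nb", Y_GRID, p_nb) - log_density("poisson", Y_GRID, p_poi)
    assert np.max(np.abs(d)) < 1e-5


def test_weibull_density_at_scale_point():
    # f(scale) = (k/scale) * e^{-1}
    for k, scale in [(2.0, 3.0), (1.3, 5.5)]:
        got = log_density("weibull", scale, ParameterSet([np.log(scale)], k))
        assert got == pytest.approx(np.log(k / scale) - 1.0, abs=1e-12)


class TestCmpNormalizer:
    def test_poisson_case(self):
        assert cmp_normalizer(2.0, 1.0) == pytest.approx(math.exp(2.0), rel=1e-10)

    def test_brute_force_sum(self):
        # direct summation of 0.5^j / (j!)^2 for j = 0..50
        brute = math.fsum(0.5**j / math.factorial(j) ** 2 for j in range(51))
        assert cmp_normalizer(0.5, 2.0) == pytest.approx(brute, rel=1e-10)

    def test_large_nu_limit(self):
        # only the j=0,1 terms survive: Z -> 1 + lambda
        assert cmp_normalizer(0.3, 60.0) == pytest.approx(1.3, rel=1e-8)

    def test_nonconvergence_raises(self):
        with pytest.raises(NumericalError):
            cmp_normalizer(1e12, 0.01)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            cmp_normalizer(-1.0, 1.0)
        with pytest.raises(DomainError):
            cmp_normalizer(2.0, 0.0)


class TestFamilyMean:
    def test_gp_closed_form(self):
        # theta/(1-delta) with theta = mu(1-delta): mean is just mu
        assert family_mean("gp", ParameterSet([np.log(4.0)], 0.5)) == pytest.approx(4.0)

    def test_exponential_is_weibull_shape_one(self):
        assert family_mean("weibull", ParameterSet([np.log(3.0)], 1.0)) == pytest.approx(3.0)

    def test_cmp_poisson_case(self):
        assert family_mean("cmp", ParameterSet([np.log(2.0)], 1.0)) == pytest.approx(2.0, abs=1e-8)

    def test_lognormal(self):
        assert family_mean("lognormal", ParameterSet([1.0], 0.5)) == pytest.approx(
            np.exp(1.0 + 0.125)
        )


@pytest.mark.parametrize(
    "family,params",
    [
        ("poisson", ParameterSet([np.log(3.0)])),
        ("nb", ParameterSet([np.log(3.0)], 0.5)),
        ("cmp", ParameterSet([np.log(3.0)], 0.7)),
        ("gp", ParameterSet([np.log(3.0)], 0.4)),
    ],
)
def test_count_pmf_normalizes(family, params):
    y = np.arange(0, 501)
    total = np.sum(np.exp(log_density(family, y, params)))
    assert total == pytest.approx(1.0, abs=1e-8)


def test_gp_moments_match_brute_force_pmf():
    # closed forms mean = theta/(1-delta), var = theta/(1-delta)^3 against
    # direct summation of the pmf over 0..500
    theta, delta = 2.0, 0.3
    mu = theta / (1 - delta)
    params = ParameterSet([np.log(mu)], delta)
    y = np.arange(0, 501)
    pmf = np.exp(log_density("gp", y, params))
    m1 = float(np.sum(y * pmf))
    m2 = float(np.sum(y**2 * pmf))
    assert m1 == pytest.approx(mu, rel=1e-10)
    assert m2 - m1**2 == pytest.approx(theta / (1 - delta) ** 3, rel=1e-10)


class TestHighPrecisionOracle:
    """log_density against an independent extended-precision evaluation."""

    @pytest.mark.parametrize("y", [0, 1, 4, 11])
    def test_gp_vs_sympy(self, y):
        import sympy as sp

        delta, mu = sp.Rational(3, 10), sp.Integer(5)
        theta = mu * (1 - delta)
        pmf = theta * (theta + delta * y) ** (y - 1) * sp.exp(-(theta + delta * y)) / sp.factorial(y)
        expected = float(sp.log(pmf).evalf(40))
        got = log_density("gp", y, ParameterSet([np.log(5.0)], 0.3))
        assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("y", [0, 2, 9])
    def test_cmp_vs_sympy(self, y):
        import sympy as sp

        lam, nu = sp.Rational(2), sp.Rational(7, 10)
        z = sum(lam**j / sp.factorial(j) ** nu for j in range(400))
        pmf = lam**y / sp.factorial(y) ** nu / z
        expected = float(sp.log(pmf).evalf(40))
        got = log_density("cmp", y, ParameterSet([np.log(2.0)], 0.7))
        assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("y", [0, 3, 17])
    def test_nb_vs_sympy(self, y):
        import sympy as sp

        mu, alpha = sp.Integer(4), sp.Rational(1, 2)
        r = 1 / alpha
        p = r / (r + mu)
        pmf = sp.gamma(y + r) / (sp.gamma(r) * sp.factorial(y)) * p**r * (1 - p) ** y
        expected = float(sp.log(pmf).evalf(40))
        got = log_density("nb", y, ParameterSet([np.log(4.0)], 0.5))
        assert got == pytest.approx(expected, abs=1e-10)


class TestSamplerMatchesDensity:
    """Empirical distribution of draws vs the implemented log-density."""

    N = 100_000
    ALPHA = 0.001

    @pytest.mark.parametrize(
        "family,params",
        [
            ("poisson", ParameterSet([np.log(4.0)])),
            ("nb", ParameterSet([np.log(4.0)], 0.5)),
            ("cmp", ParameterSet([np.log(3.0)], 0.7)),
            ("gp", ParameterSet([np.log(4.0)], 0.35)),
        ],
    )
    def test_count_families_chi_square(self, family, params):
        from skewfit import simulate_from_family

        draws = simulate_from_family(family, params, n=self.N, seed=11)
        y = np.arange(0, 200)
        pmf = np.exp(log_density(family, y, params))
        # merge the tail so all expected counts are >= 5
        exp_counts = pmf * self.N
        cut = np.max(np.nonzero(exp_counts >= 5)[0]) + 1
        obs = np.bincount(draws, minlength=200)[:200].astype(float)
        obs_b = np.append(obs[:cut], obs[cut:].sum())
        exp_b = np.append(exp_counts[:cut], exp_counts[cut:].sum())
        exp_b *= obs_b.sum() / exp_b.sum()
        chi2, p = stats.chisquare(obs_b, exp_b)
        assert p > self.ALPHA

    @pytest.mark.parametrize(
        "family,params",
        [
            ("normal", ParameterSet([2.0], 1.5)),
            ("lognormal", ParameterSet([1.0], 0.6)),
            ("gamma", ParameterSet([np.log(5.0)], 2.0)),
            ("weibull", ParameterSet([np.log(5.0)], 1.4)),
        ],
    )
    def test_continuous_families_ks(self, family, params):
        from skewfit import simulate_from_family

        draws = simulate_from_family(family, params, n=self.N, seed=13)
        fam = get_family(family)
        stat, p = stats.kstest(draws, lambda q: fam.cdf(q, params.beta[0], params.aux))
        assert p > self.ALPHA


class TestDomainValidation:
    def test_unknown_family(self):
        with pytest.raises(DomainError):
            get_family("zeta")

    def test_count_support_rejects_negative_and_fractional(self):
        with pytest.raises(DomainError):
            log_density("poisson", -1, ParameterSet([0.0]))
        with pytest.raises(DomainError):
            log_density("gp", 2.5, ParameterSet([0.0], 0.1))

    def test_positive_support_rejects_zero(self):
        with pytest.raises(DomainError):
            log_density("lognormal", 0.0, ParameterSet([0.0], 1.0))

    @pytest.mark.parametrize(
        "family,aux",
        [("normal", -1.0), ("gamma", 0.0), ("nb", -0.1), ("cmp", 0.0), ("gp", 1.0)],
    )
    def test_inadmissible_aux(self, family, aux):
        with pytest.raises(DomainError):
            log_density(family, 1.0 if family != "gp" else 1, ParameterSet([0.0], aux))


def test_every_family_registered():
    for name in FAMILY_NAMES:
        fam = get_family(name)
        assert fam.name == name
        assert fam.support in ("reals", "positive", "counts")
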