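"""Pair-copula families: densities, h-functions, tau relations, fitting.

Closed-form copula CDFs are re-implemented here (independently of the
package) so that h-functions and densities can be checked against finite
differences of the CDF.
"""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtri

from vinepop.bicop import (
    FAMILIES,
    BivariateCopula,
    fit_bicop,
    frank_tau,
    hfunc,
    hinv,
    par_to_tau,
    simulate_bicop,
)

#: representative (family, parameters) pairs with moderate dependence
CASES = [
    ("gaussian", [0.5]),
    ("student_t", [0.5, 6.0]),
    ("clayton", [2.0]),
    ("gumbel", [1.8]),
    ("frank", [4.0]),
    ("joe", [2.2]),
    ("bb1", [0.7, 1.5]),
    ("bb8", [3.0, 0.7]),
]


def copula_cdf(family, u, v, par):
    """Independent closed-form CDFs (numerical quadrature for student_t)."""
    if family == "independence":
        return u * v
    if family == "gaussian":
        (rho,) = par
        return stats.multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([ndtri(u), ndtri(v)])
    if family == "student_t":
        rho, nu = par
        from scipy.integrate import dblquad

        x, y = stats.t.ppf(u, nu), stats.t.ppf(v, nu)
        s2 = 1 - rho * rho
        c = math.exp(math.lgamma((nu + 2) / 2) - math.lgamma(nu / 2)) / (nu * math.pi * math.sqrt(s2))

        def dens(t2, t1):
            return c * (1 + (t1 * t1 + t2 * t2 - 2 * rho * t1 * t2) / (nu * s2)) ** (-(nu + 2) / 2)

        val, _ = dblquad(dens, -30, x, -30, y, epsabs=1e-10, epsrel=1e-10)
        return val
    if family == "clayton":
        (th,) = par
        return (u**-th + v**-th - 1) ** (-1 / th)
    if family == "gumbel":
        (th,) = par
        return math.exp(-(((-math.log(u)) ** th + (-math.log(v)) ** th) ** (1 / th)))
    if family == "frank":
        (th,) = par
        return -1 / th * math.log(1 + math.expm1(-th * u) * math.expm1(-th * v) / math.expm1(-th))
    if family == "joe":
        (th,) = par
        x, y = (1 - u) ** th, (1 - v) ** th
        return 1 - (x + y - x * y) ** (1 / th)
    if family == "bb1":
        th, de = par
        s = (u**-th - 1) ** de + (v**-th - 1) ** de
        return (1 + s ** (1 / de)) ** (-1 / th)
    if family == "bb8":
        th, de = par
        k = lambda t: 1 - (1 - de * t) ** th
        return (1 - (1 - k(u) * k(v) / k(1.0)) ** (1 / th)) / de
    raise ValueError(family)


class TestDensity:
    def test_independence_density_is_one(self, rng):
        cop = BivariateCopula("independence")
        u, v = rng.uniform(size=(2, 50))
        assert np.allclose(cop.pdf(u, v), 1.0)

    def test_gaussian_rho_zero_reduces_to_independence(self):
        assert BivariateCopula("gaussian", 0, [0.0]).pdf(0.3, 0.7) == pytest.approx(1.0)

    @pytest.mark.parametrize("family,par", CASES)
    def test_density_matches_mixed_partial_of_cdf(self, family, par, rng):
        h = 1e-5
        for _ in range(5):
            u, v = rng.uniform(0.1, 0.9, size=2)
            fd = (
                copula_cdf(family, u + h, v + h, par)
                - copula_cdf(family, u + h, v - h, par)
                - copula_cdf(family, u - h, v + h, par)
                + copula_cdf(family, u - h, v - h, par)
            ) / (4 * h * h)
            got = float(BivariateCopula(family, 0, par).pdf(u, v))
            assert got == pytest.approx(fd, rel=2e-3, abs=2e-3)

    @pytest.mark.parametrize("family,par", CASES)
    def test_density_integrates_to_one_with_uniform_margins(self, family, par):
        """Quadrature in Gauss-transformed coordinates resolves the corners."""
        z, wz = np.polynomial.legendre.leggauss(120)
        z = 8.0 * z
        wz = 8.0 * wz
        u = stats.norm.cdf(z)
        phi = stats.norm.pdf(z)
        cop = BivariateCopula(family, 0, par)
        U, V = np.meshgrid(u, u)
        W = np.outer(wz * phi, wz * phi)
        total = float((cop.pdf(U, V) * W).sum())
        assert total == pytest.approx(1.0, abs=1e-3)
        # conditional margin: integral over v at fixed u stays 1
        for u0 in (0.2, 0.5, 0.8):
            m = float((cop.pdf(np.full_like(u, u0), u) * wz * phi).sum())
            assert m == pytest.approx(1.0, abs=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BivariateCopula("gaussian", 0, [1.5])
        with pytest.raises(ValueError):
            BivariateCopula("clayton", 0, [-1.0])
        with pytest.raises(ValueError):
            BivariateCopula("gaussian", 45, [0.5])


class TestHFunctions:
    @pytest.mark.parametrize("family,par", CASES)
    def test_hfunc_matches_cdf_derivative(self, family, par, rng):
        h = 1e-5
        cop = BivariateCopula(family, 0, par)
        for _ in range(5):
            u, v = rng.uniform(0.1, 0.9, size=2)
            fd = (copula_cdf(family, u, v + h, par) - copula_cdf(family, u, v - h, par)) / (2 * h)
            assert float(cop.hfunc(u, v, which=2)) == pytest.approx(fd, abs=1e-4)
            fd1 = (copula_cdf(family, u + h, v, par) - copula_cdf(family, u - h, v, par)) / (2 * h)
            assert float(cop.hfunc(u, v, which=1)) == pytest.approx(fd1, abs=1e-4)

    def test_independence_hfunc_identity(self, rng):
        cop = BivariateCopula("independence")
        u, v = rng.uniform(size=(2, 20))
        assert np.allclose(cop.hfunc(u, v, 2), u)
        assert np.allclose(cop.hfunc(u, v, 1), v)

    @pytest.mark.parametrize("family,par", CASES)
    def test_hfunc_boundary_behaviour(self, family, par):
        cop = BivariateCopula(family, 0, par)
        v = 0.37
        assert float(cop.hfunc(1e-9, v, 2)) < 1e-3
        assert float(cop.hfunc(1 - 1e-9, v, 2)) > 1 - 1e-3

    @pytest.mark.parametrize("family,par", CASES)
    def test_hfunc_monotone_in_conditioned_argument(self, family, par):
        cop = BivariateCopula(family, 0, par)
        u = np.linspace(0.01, 0.99, 50)
        h = cop.hfunc(u, np.full_like(u, 0.4), 2)
        assert np.all(np.diff(h) > -1e-12)

    def test_gaussian_hfunc_closed_form(self):
        rho = 0.5
        cop = BivariateCopula("gaussian", 0, [rho])
        x, y = ndtri(0.5), ndtri(0.5)
        expect = stats.norm.cdf((x - rho * y) / math.sqrt(1 - rho**2))
        assert float(cop.hfunc(0.5, 0.5, 2)) == pytest.approx(expect, abs=1e-10)


class TestHInverse:
    @pytest.mark.parametrize("family,par", CASES)
    def test_roundtrip_all_rotations(self, family, par, rng):
        rots = [0, 90, 180, 270] if FAMILIES[family].one_sided else [0]
        for rot in rots:
            cop = BivariateCopula(family, rot, par)
            p = rng.uniform(0.01, 0.99, 100)
            v = rng.uniform(0.01, 0.99, 100)
            u = cop.hinv(p, v, 2)
            assert np.max(np.abs(cop.hfunc(u, v, 2) - p)) < 1e-8
            w = cop.hinv(p, v, 1)
            assert np.max(np.abs(cop.hfunc(v, w, 1) - p)) < 1e-8

    def test_independence_hinv_identity(self, rng):
        cop = BivariateCopula("independence")
        p, v = rng.uniform(size=(2, 20))
        assert np.allclose(cop.hinv(p, v, 2), p)

    def test_clayton_closed_form_equals_bisection(self, rng):
        """The analytic Clayton inverse agrees with generic bisection."""
        from vinepop.bicop import Clayton, _Family

        par = [2.0]
        p = rng.uniform(0.05, 0.95, 50)
        v = rng.uniform(0.05, 0.95, 50)
        closed = Clayton.h2inv(p, v, par)
        generic = _Family.h2inv.__func__(Clayton, p, v, par)
        assert np.max(np.abs(closed - generic)) < 1e-8


class TestTau:
    def test_closed_forms(self):
        assert par_to_tau(BivariateCopula("clayton", 0, [2.0])) == pytest.approx(0.5)
        assert par_to_tau(BivariateCopula("gaussian", 0, [0.0])) == pytest.approx(0.0)
        assert par_to_tau(BivariateCopula("gumbel", 0, [1.0])) == pytest.approx(0.0)
        assert par_to_tau(BivariateCopula("gaussian", 0, [0.8])) == pytest.approx(
            2 / math.pi * math.asin(0.8)
        )
        assert par_to_tau(BivariateCopula("bb1", 0, [0.5, 2.0])) == pytest.approx(
            1 - 2 / (2.0 * 2.5)
        )

    def test_rotation_flips_sign(self):
        t0 = par_to_tau(BivariateCopula("clayton", 0, [2.0]))
        assert par_to_tau(BivariateCopula("clayton", 90, [2.0])) == pytest.approx(-t0)
        assert par_to_tau(BivariateCopula("clayton", 180, [2.0])) == pytest.approx(t0)

    def test_frank_tau_odd_and_monotone(self):
        assert frank_tau(5.0) == pytest.approx(-frank_tau(-5.0))
        taus = [frank_tau(t) for t in (0.5, 2.0, 5.0, 10.0)]
        assert all(a < b for a, b in zip(taus, taus[1:]))

    @pytest.mark.parametrize("family,par", [("joe", [2.2]), ("bb8", [3.0, 0.7])])
    def test_numeric_tau_matches_monte_carlo(self, family, par):
        cop = BivariateCopula(family, 0, par)
        s = cop.simulate(30_000, seed=11)
        mc = stats.kendalltau(s[:, 0], s[:, 1]).statistic
        assert cop.tau() == pytest.approx(mc, abs=0.012)


class TestSimulate:
    def test_empty_and_deterministic(self):
        cop = BivariateCopula("gumbel", 0, [2.0])
        assert simulate_bicop(cop, 0).shape == (0, 2)
        assert np.array_equal(simulate_bicop(cop, 50, seed=3), simulate_bicop(cop, 50, seed=3))

    def test_gaussian_tau_recovery(self):
        cop = BivariateCopula("gaussian", 0, [0.8])
        s = simulate_bicop(cop, 10_000, seed=5)
        mc = stats.kendalltau(s[:, 0], s[:, 1]).statistic
        assert mc == pytest.approx(2 / math.pi * math.asin(0.8), abs=0.03)

    @pytest.mark.parametrize("family,par", CASES)
    def test_uniform_margins(self, family, par):
        s = BivariateCopula(family, 0, par).simulate(10_000, seed=9)
        assert stats.kstest(s[:, 0], "uniform").statistic < 0.02
        assert stats.kstest(s[:, 1], "uniform").statistic < 0.02


class TestFit:
    def test_clayton_recovery(self):
        s = BivariateCopula("clayton", 0, [2.0]).simulate(5000, seed=21)
        fit = fit_bicop(s[:, 0], s[:, 1])
        assert fit.family == "clayton" and fit.rotation == 0
        assert fit.tau() == pytest.approx(0.5, abs=0.05)

    def test_rotated_clayton_recovers_negative_dependence(self):
        s = BivariateCopula("clayton", 90, [2.0]).simulate(5000, seed=22)
        fit = fit_bicop(s[:, 0], s[:, 1])
        assert fit.tau() == pytest.approx(-0.5, abs=0.05)
        assert fit.rotation in (90, 270)

    def test_null_recovery_on_independent_data(self, rng):
        u, v = rng.uniform(size=(2, 5000))
        fit = fit_bicop(u, v)
        assert fit.family == "independence" or abs(fit.tau()) < 0.05

    def test_duplicate_rows_equal_double_weights(self):
        s = BivariateCopula("gaussian", 0, [0.5]).simulate(800, seed=30)
        f_dup = fit_bicop(
            np.concatenate([s[:, 0]] * 2), np.concatenate([s[:, 1]] * 2), family_set=["gaussian"]
        )
        f_w = fit_bicop(s[:, 0], s[:, 1], weights=np.full(800, 2.0), family_set=["gaussian"])
        assert f_dup.parameters[0] == pytest.approx(f_w.parameters[0], abs=1e-6)

    def test_small_sample_falls_back_to_independence(self, rng):
        u, v = rng.uniform(size=(2, 10))
        assert fit_bicop(u, v).family == "independence"

    def test_selected_aic_beats_independence(self):
        s = BivariateCopula("gumbel", 0, [2.0]).simulate(2000, seed=31)
        fit = fit_bicop(s[:, 0], s[:, 1])
        assert fit.aic <= 0.0  # independence AIC is exactly 0

    def test_aic_identity(self):
        cop = BivariateCopula("student_t", 0, [0.4, 8.0], loglik=123.0)
        assert cop.aic == pytest.approx(2 * 2 - 2 * 123.0)

    def test_serialization_roundtrip(self):
        cop = BivariateCopula("bb1", 180, [0.7, 1.5], loglik=10.0, n_fit=99)
        cop2 = BivariateCopula.from_dict(cop.to_dict())
        assert cop2.family == "bb1" and cop2.rotation == 180
        assert cop2.parameters == cop.parameters
        assert cop2.aic == pytest.approx(cop.aic)
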