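"""Parametric bivariate copula families.

Implements density, conditional distribution (h-) functions and their
inverses, Kendall's-tau relations, weighted maximum-likelihood fitting and
AIC-based family selection for the families

    independence, gaussian, student_t, clayton, gumbel, frank, joe,
    bb1 (Clayton-Gumbel) and bb8 (Joe-Frank),

with 90/180/270-degree rotations of the one-sided (asymmetric-tail)
families.  All base families are exchangeable, so only the h-function with
respect to the second argument is implemented per family; the other
direction and the rotations are obtained by argument reflection.

Conventions
-----------
``hfunc(u, v, which=2)`` is the conditional CDF ``P(U <= u | V = v) =
dC(u,v)/dv``;  ``which=1`` conditions on the first argument.  ``hinv``
inverts the h-function in its non-conditioning argument, which is the step
needed for inverse-Rosenblatt simulation.

Rotations follow the usual convention: 180 degrees is the survival copula,
90 and 270 reflect one argument and therefore carry negative dependence
(Kendall's tau flips sign).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.integrate import quad
from scipy.special import ndtr, ndtri, gammaln

log = logging.getLogger(__name__)

EPS = 1e-10
LOGPDF_FLOOR = -700.0
MIN_FIT_N = 20

#: canonical family order, used for deterministic AIC tie-breaking
FAMILY_ORDER = [
    "independence",
    "gaussian",
    "student_t",
    "clayton",
    "gumbel",
    "frank",
    "joe",
    "bb1",
    "bb8",
]


def _clamp(u):
    return np.clip(np.asarray(u, dtype=float), EPS, 1.0 - EPS)


# ---------------------------------------------------------------------------
# family implementations (base, unrotated, exchangeable)
# ---------------------------------------------------------------------------


class _Family:
    name: str
    n_params: int
    bounds: list[tuple[float, float]]
    one_sided: bool = False  # True -> rotations 90/180/270 are distinct

    @staticmethod
    def logpdf(u, v, par):  # pragma: no cover - interface
        raise NotImplementedError

    @staticmethod
    def h2(u, v, par):  # P(U<=u | V=v)
        raise NotImplementedError

    @classmethod
    def h2inv(cls, p, v, par):
        """Solve h2(u, v) = p for u; bisection default (h2 increasing in u)."""
        p = _clamp(p)
        v = _clamp(v)
        lo = np.full_like(p, EPS)
        hi = np.full_like(p, 1.0 - EPS)
        for _ in range(52):
            mid = 0.5 * (lo + hi)
            too_low = cls.h2(mid, v, par) < p
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        return 0.5 * (lo + hi)

    @staticmethod
    def tau(par) -> float:
        raise NotImplementedError

    @staticmethod
    def par_init(tau: float) -> list[float]:
        raise NotImplementedError


class Independence(_Family):
    name = "independence"
    n_params = 0
    bounds: list[tuple[float, float]] = []

    @staticmethod
    def logpdf(u, v, par):
        return np.zeros(np.broadcast(u, v).shape)

    @staticmethod
    def h2(u, v, par):
        return _clamp(u)

    @classmethod
    def h2inv(cls, p, v, par):
        return _clamp(p)

    @staticmethod
    def tau(par):
        return 0.0

    @staticmethod
    def par_init(tau):
        return []


class Gaussian(_Family):
    name = "gaussian"
    n_params = 1
    bounds = [(-0.999, 0.999)]

    @staticmethod
    def logpdf(u, v, par):
        (rho,) = par
        x = ndtri(_clamp(u))
        y = ndtri(_clamp(v))
        s2 = 1.0 - rho * rho
        return -0.5 * math.log(s2) - (rho * rho * (x * x + y * y) - 2.0 * rho * x * y) / (2.0 * s2)

    @staticmethod
    def h2(u, v, par):
        (rho,) = par
        x = ndtri(_clamp(u))
        y = ndtri(_clamp(v))
        return _clamp(ndtr((x - rho * y) / math.sqrt(1.0 - rho * rho)))

    @classmethod
    def h2inv(cls, p, v, par):
        (rho,) = par
        y = ndtri(_clamp(v))
        x = ndtri(_clamp(p)) * math.sqrt(1.0 - rho * rho) + rho * y
        return _clamp(ndtr(x))

    @staticmethod
    def tau(par):
        return 2.0 / math.pi * math.asin(par[0])

    @staticmethod
    def par_init(tau):
        return [math.sin(math.pi * np.clip(tau, -0.95, 0.95) / 2.0)]


class StudentT(_Family):
    name = "student_t"
    n_params = 2
    bounds = [(-0.999, 0.999), (2.0, 50.0)]

    @staticmethod
    def logpdf(u, v, par):
        rho, nu = par
        x = stats.t.ppf(_clamp(u), nu)
        y = stats.t.ppf(_clamp(v), nu)
        s2 = 1.0 - rho * rho
        q = (x * x + y * y - 2.0 * rho * x * y) / (nu * s2)
        log_f2 = (
            gammaln((nu + 2.0) / 2.0)
            - gammaln(nu / 2.0)
            - math.log(nu * math.pi)
            - 0.5 * math.log(s2)
            - (nu + 2.0) / 2.0 * np.log1p(q)
        )
        return log_f2 - stats.t.logpdf(x, nu) - stats.t.logpdf(y, nu)

    @staticmethod
    def h2(u, v, par):
        rho, nu = par
        x = stats.t.ppf(_clamp(u), nu)
        y = stats.t.ppf(_clamp(v), nu)
        scale = np.sqrt((nu + y * y) * (1.0 - rho * rho) / (nu + 1.0))
        return _clamp(stats.t.cdf((x - rho * y) / scale, nu + 1.0))

    @classmethod
    def h2inv(cls, p, v, par):
        rho, nu = par
        y = stats.t.ppf(_clamp(v), nu)
        scale = np.sqrt((nu + y * y) * (1.0 - rho * rho) / (nu + 1.0))
        x = stats.t.ppf(_clamp(p), nu + 1.0) * scale + rho * y
        return _clamp(stats.t.cdf(x, nu))

    @staticmethod
    def tau(par):
        return 2.0 / math.pi * math.asin(par[0])

    @staticmethod
    def par_init(tau):
        return [math.sin(math.pi * np.clip(tau, -0.95, 0.95) / 2.0), 6.0]


def _clayton_logS(u, v, theta):
    """log(u^-t + v^-t - 1) computed in log space to avoid overflow."""
    a = -theta * np.log(u)
    b = -theta * np.log(v)
    m = np.maximum(a, b)
    return m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))


class Clayton(_Family):
    name = "clayton"
    n_params = 1
    bounds = [(1e-4, 28.0)]
    one_sided = True

    @staticmethod
    def logpdf(u, v, par):
        (th,) = par
        u = _clamp(u)
        v = _clamp(v)
        logS = _clayton_logS(u, v, th)
        return math.log1p(th) - (1.0 + th) * (np.log(u) + np.log(v)) - (2.0 + 1.0 / th) * logS

    @staticmethod
    def h2(u, v, par):
        (th,) = par
        u = _clamp(u)
        v = _clamp(v)
        logS = _clayton_logS(u, v, th)
        return _clamp(np.exp(-(1.0 + th) * np.log(v) - (1.0 + 1.0 / th) * logS))

    @classmethod
    def h2inv(cls, p, v, par):
        (th,) = par
        p = _clamp(p)
        v = _clamp(v)
        # u = (v^-t * (p^{-t/(1+t)} - 1) + 1)^{-1/t}, in log space
        log_r_minus_1 = np.log(np.expm1(-th / (1.0 + th) * np.log(p)))
        log_term = np.logaddexp(-th * np.log(v) + log_r_minus_1, 0.0)
        return _clamp(np.exp(-log_term / th))

    @staticmethod
    def tau(par):
        return par[0] / (par[0] + 2.0)

    @staticmethod
    def par_init(tau):
        t = min(abs(tau), 0.92)
        return [max(2.0 * t / (1.0 - t), 1e-3)]


class Gumbel(_Family):
    name = "gumbel"
    n_params = 1
    bounds = [(1.0, 20.0)]
    one_sided = True

    @staticmethod
    def logpdf(u, v, par):
        (th,) = par
        u = _clamp(u)
        v = _clamp(v)
        lx = np.log(-np.log(u))  # log(~x), ~x = -log u > 0
        ly = np.log(-np.log(v))
        logS = np.logaddexp(th * lx, th * ly)
        A = np.exp(logS / th)
        return (
            -A
            + (th - 1.0) * (lx + ly)
            - np.log(u)
            - np.log(v)
            + (1.0 / th - 2.0) * logS
            + np.log(A + th - 1.0)
        )

    @staticmethod
    def h2(u, v, par):
        (th,) = par
        u = _clamp(u)
        v = _clamp(v)
        lx = np.log(-np.log(u))
        ly = np.log(-np.log(v))
        logS = np.logaddexp(th * lx, th * ly)
        A = np.exp(logS / th)
        return _clamp(np.exp(-A - np.log(v) + (th - 1.0) * ly + (1.0 / th - 1.0) * logS))

    @staticmethod
    def tau(par):
        return 1.0 - 1.0 / par[0]

    @staticmethod
    def par_init(tau):
        return [min(1.0 / max(1.0 - abs(tau), 0.06), 19.0)]


class Frank(_Family):
    name = "frank"
    n_params = 1
    bounds = [(-35.0, 35.0)]

    @staticmethod
    def logpdf(u, v, par):
        (th,) = par
        if abs(th) < 1e-5:
            return np.zeros(np.broadcast(u, v).shape)
        u = _clamp(u)
        v = _clamp(v)
        E = math.expm1(-th)
        Eu = np.expm1(-th * u)
        Ev = np.expm1(-th * v)
        num = -th * E  # positive for either sign of theta
        return math.log(num) - th * (u + v) - 2.0 * np.log(np.abs(E + Eu * Ev))

    @staticmethod
    def h2(u, v, par):
        (th,) = par
        if abs(th) < 1e-5:
            return _clamp(u)
        u = _clamp(u)
        v = _clamp(v)
        E = math.expm1(-th)
        Eu = np.expm1(-th * u)
        Ev = np.expm1(-th * v)
        return _clamp((1.0 + Ev) * Eu / (E + Eu * Ev))

    @classmethod
    def h2inv(cls, p, v, par):
        (th,) = par
        if abs(th) < 1e-5:
            return _clamp(p)
        p = _clamp(p)
        v = _clamp(v)
        E = math.expm1(-th)
        Ev = np.expm1(-th * v)
        Eu = p * E / (1.0 + Ev - p * Ev)
        return _clamp(-np.log1p(Eu) / th)

    @staticmethod
    def tau(par):
        return frank_tau(par[0])

    @staticmethod
    def par_init(tau):
        if abs(tau) < 1e-3:
            return [math.copysign(1e-3, tau) if tau else 1e-3]
        th = optimize.brentq(lambda t: frank_tau(t) - tau, -34.9, 34.9, xtol=1e-6)
        return [float(np.clip(th, -34.9, 34.9))]


def _debye1(x: float) -> float:
    if x == 0:
        return 1.0
    val, _ = quad(lambda t: t / math.expm1(t), 0.0, abs(x), limit=200)
    return val / abs(x)


def frank_tau(theta: float) -> float:
    """Kendall's tau of the Frank copula via the first Debye function."""
    if abs(theta) < 1e-8:
        return 0.0
    t = 1.0 - 4.0 / abs(theta) * (1.0 - _debye1(abs(theta)))
    return math.copysign(t, theta)


class Joe(_Family):
    name = "joe"
    n_params = 1
    bounds = [(1.0, 20.0)]
    one_sided = True

    @staticmethod
    def _T(u, v, th):
        x = np.exp(th * np.log1p(-u))  # (1-u)^theta
        y = np.exp(th * np.log1p(-v))
        return x + y - x * y, x, y

    @staticmethod
    def logpdf(u, v, par):
        (th,) = par
        u = _clamp(u)
        v = _clamp(v)
        T, _, _ = Joe._T(u, v, th)
        return (
            (1.0 / th - 2.0) * np.log(T)
            + (th - 1.0) * (np.log1p(-u) + np.log1p(-v))
            + np.log(th - 1.0 + T)
        )

    @staticmethod
    def h2(u, v, par):
        (th,) = par
        u = _clamp(u)
        v = _clamp(v)
        T, x, _ = Joe._T(u, v, th)
        return _clamp(np.exp((1.0 / th - 1.0) * np.log(T) + (th - 1.0) * np.log1p(-v)) * (1.0 - x))

    @staticmethod
    def tau(par):
        (th,) = par
        if th <= 1.0 + 1e-12:
            return 0.0

        def phi_over_dphi(t):
            g = 1.0 - (1.0 - t) ** th  # in (0,1)
            return math.log(g) * g / (th * (1.0 - t) ** (th - 1.0))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val, _ = quad(phi_over_dphi, 0.0, 1.0, limit=200)
        return 1.0 + 4.0 * val

    @staticmethod
    def par_init(tau):
        return [min(1.0 / max(1.0 - abs(tau), 0.06), 19.0)]


class BB1(_Family):
    """Clayton-Gumbel: Archimedean with generator (t^-theta - 1)^delta."""

    name = "bb1"
    n_params = 2
    bounds = [(1e-4, 7.0), (1.0, 7.0)]
    one_sided = True

    @staticmethod
    def _log_g(t, th):
        # log(t^-theta - 1) = log(1 - t^theta) - theta*log(t)
        return np.log(-np.expm1(th * np.log(t))) - th * np.log(t)

    @staticmethod
    def _log_neg_dphi(t, log_g, th, de):
        return math.log(de * th) + (de - 1.0) * log_g - (th + 1.0) * np.log(t)

    @staticmethod
    def _parts(u, v, par):
        th, de = par
        u = _clamp(u)
        v = _clamp(v)
        lg_u = BB1._log_g(u, th)
        lg_v = BB1._log_g(v, th)
        log_s = np.logaddexp(de * lg_u, de * lg_v)  # log(phi(u)+phi(v))
        lse = np.logaddexp(0.0, log_s / de)  # log(1 + s^{1/delta})
        log_C = -lse / th
        log_g_C = log_s / de  # g(C) = s^{1/delta}
        return u, v, lg_u, lg_v, log_C, log_g_C, lse

    @staticmethod
    def logpdf(u, v, par):
        th, de = par
        u, v, lg_u, lg_v, log_C, log_g_C, lse = BB1._parts(u, v, par)
        # phi''(C): C^theta = 1/(1 + s^{1/delta}) = exp(-lse)
        bracket = (de - 1.0) * th + (th + 1.0) * (1.0 - np.exp(-lse))
        log_ddphi_C = math.log(de * th) + (de - 2.0) * log_g_C - (2.0 * th + 2.0) * log_C + np.log(bracket)
        return (
            log_ddphi_C
            + BB1._log_neg_dphi(u, lg_u, th, de)
            + BB1._log_neg_dphi(v, lg_v, th, de)
            - 3.0 * BB1._log_neg_dphi(np.exp(log_C), log_g_C, th, de)
        )

    @staticmethod
    def h2(u, v, par):
        th, de = par
        u, v, lg_u, lg_v, log_C, log_g_C, lse = BB1._parts(u, v, par)
        log_h = BB1._log_neg_dphi(v, lg_v, th, de) - BB1._log_neg_dphi(np.exp(log_C), log_g_C, th, de)
        return _clamp(np.exp(log_h))

    @staticmethod
    def tau(par):
        th, de = par
        return 1.0 - 2.0 / (de * (th + 2.0))

    @staticmethod
    def par_init(tau):
        de = 1.5
        th = 2.0 / (de * max(1.0 - abs(tau), 0.08)) - 2.0
        return [float(np.clip(th, 0.05, 6.9)), de]


class BB8(_Family):
    """Joe-Frank: generator -log((1 - (1-delta*t)^theta) / (1 - (1-delta)^theta)).

    Everything is evaluated through log k(t) with k(t) = 1 - (1 - delta*t)^theta.
    The copula value C never has to be formed explicitly: the generator identity
    gives k(C) = k(u)k(v)/eta and (1 - delta*C) = (1 - k(C))^(1/theta), which
    avoids the catastrophic cancellation of 1 - C near the upper corner.
    """

    name = "bb8"
    n_params = 2
    bounds = [(1.0, 8.0), (1e-4, 1.0)]
    one_sided = True

    @staticmethod
    def _log_k(t, th, de):
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(th * np.log1p(-de * t)))

    @staticmethod
    def _log_dk_from_1mdt(log_1mdt, th, de):
        # dk(t) = theta*delta*(1-delta*t)^(theta-1)
        return math.log(th * de) + (th - 1.0) * log_1mdt

    @staticmethod
    def _parts(u, v, par):
        th, de = par
        log_eta = float(BB8._log_k(1.0, th, de))
        log_ku = BB8._log_k(u, th, de)
        log_kv = BB8._log_k(v, th, de)
        log_kC = log_ku + log_kv - log_eta  # identity k(C) = k(u)k(v)/eta
        with np.errstate(divide="ignore"):
            log_w = np.log(-np.expm1(log_kC)) / th  # w = 1 - delta*C
        return log_ku, log_kv, log_kC, log_w

    @staticmethod
    def logpdf(u, v, par):
        th, de = par
        u = _clamp(u)
        v = _clamp(v)
        log_ku, log_kv, log_kC, log_w = BB8._parts(u, v, par)
        inner = np.exp(th * log_w)  # (1 - delta*C)^theta = 1 - k(C)
        # phi''(C) = theta*delta^2*w^(theta-2)*(theta-1+inner)/k(C)^2
        log_ddphi = (
            math.log(th)
            + 2.0 * math.log(de)
            + (th - 2.0) * log_w
            + np.log(th - 1.0 + inner)
            - 2.0 * log_kC
        )
        log_dku = BB8._log_dk_from_1mdt(np.log1p(-de * u), th, de)
        log_dkv = BB8._log_dk_from_1mdt(np.log1p(-de * v), th, de)
        log_dkC = BB8._log_dk_from_1mdt(log_w, th, de)
        with np.errstate(all="ignore"):
            out = log_ddphi + log_dku - log_ku + log_dkv - log_kv + 3.0 * (log_kC - log_dkC)
        return np.maximum(np.where(np.isfinite(out), out, LOGPDF_FLOOR), LOGPDF_FLOOR)

    @staticmethod
    def h2(u, v, par):
        th, de = par
        u = _clamp(u)
        v = _clamp(v)
        _, log_kv, log_kC, log_w = BB8._parts(u, v, par)
        log_dkv = BB8._log_dk_from_1mdt(np.log1p(-de * v), th, de)
        log_dkC = BB8._log_dk_from_1mdt(log_w, th, de)
        return _clamp(np.exp(log_dkv - log_kv + log_kC - log_dkC))

    @staticmethod
    def tau(par):
        th, de = par
        if th <= 1.0 + 1e-12:
            return 0.0
        log_eta = float(BB8._log_k(1.0, th, de))

        def phi_over_dphi(t):
            log_k = float(BB8._log_k(t, th, de))
            dk = th * de * (1.0 - de * t) ** (th - 1.0)
            return (log_k - log_eta) * math.exp(log_k) / dk

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val, _ = quad(phi_over_dphi, 0.0, 1.0, limit=200)
        return 1.0 + 4.0 * val

    @staticmethod
    def par_init(tau):
        return [float(np.clip(1.0 + 4.0 * abs(tau), 1.05, 7.9)), 0.8]


FAMILIES: dict[str, type[_Family]] = {
    f.name: f
    for f in (Independence, Gaussian, StudentT, Clayton, Gumbel, Frank, Joe, BB1, BB8)
}

DEFAULT_FAMILY_SET = list(FAMILY_ORDER)


# ---------------------------------------------------------------------------
# rotation wrapper and public copula object
# ---------------------------------------------------------------------------


@dataclass
class BivariateCopula:
    """A fitted (or specified) parametric pair copula with rotation."""

    family: str
    rotation: int = 0
    parameters: list[float] = field(default_factory=list)
    loglik: float = 0.0
    n_fit: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown copula family {self.family!r}")
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError(f"rotation must be one of 0/90/180/270, got {self.rotation}")
        fam = FAMILIES[self.family]
        self.parameters = [float(p) for p in self.parameters]
        if len(self.parameters) != fam.n_params:
            raise ValueError(
                f"{self.family} takes {fam.n_params} parameter(s), got {len(self.parameters)}"
            )
        for p, (lo, hi) in zip(self.parameters, fam.bounds):
            if not (lo - 1e-12 <= p <= hi + 1e-12):
                raise ValueError(
                    f"{self.family} parameter {p} outside admissible range [{lo}, {hi}]"
                )

    # -- derived quantities ---------------------------------------------
    @property
    def n_params(self) -> int:
        return FAMILIES[self.family].n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def tau(self) -> float:
        t = FAMILIES[self.family].tau(self.parameters)
        return -t if self.rotation in (90, 270) else t

    # -- density ---------------------------------------------------------
    def logpdf(self, u, v) -> np.ndarray:
        fam = FAMILIES[self.family]
        u = _clamp(u)
        v = _clamp(v)
        if self.rotation == 90:
            u = 1.0 - u
        elif self.rotation == 180:
            u, v = 1.0 - u, 1.0 - v
        elif self.rotation == 270:
            v = 1.0 - v
        out = fam.logpdf(u, v, self.parameters)
        return np.maximum(out, LOGPDF_FLOOR)

    def pdf(self, u, v) -> np.ndarray:
        return np.exp(self.logpdf(u, v))

    # -- h-functions ------------------------------------------------------
    def hfunc(self, u, v, which: int = 2) -> np.ndarray:
        """Conditional CDF: which=2 -> P(U<=u|V=v), which=1 -> P(V<=v|U=u)."""
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        fam = FAMILIES[self.family]
        u = _clamp(u)
        v = _clamp(v)
        par = self.parameters
        r = self.rotation
        if which == 2:
            if r == 0:
                return fam.h2(u, v, par)
            if r == 180:
                return _clamp(1.0 - fam.h2(1.0 - u, 1.0 - v, par))
            if r == 90:
                return _clamp(1.0 - fam.h2(1.0 - u, v, par))
            return fam.h2(u, 1.0 - v, par)  # 270
        # which == 1: exchangeable base, so h1(v|u) = h2 with swapped args
        if r == 0:
            return fam.h2(v, u, par)
        if r == 180:
            return _clamp(1.0 - fam.h2(1.0 - v, 1.0 - u, par))
        if r == 90:
            return fam.h2(v, 1.0 - u, par)
        return _clamp(1.0 - fam.h2(1.0 - v, u, par))  # 270

    def hinv(self, p, cond, which: int = 2) -> np.ndarray:
        """Inverse of hfunc in its non-conditioning argument.

        which=2: returns u with hfunc(u, cond, 2) = p  (cond plays v);
        which=1: returns v with hfunc(cond, v, 1) = p  (cond plays u).
        """
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        fam = FAMILIES[self.family]
        p = _clamp(p)
        cond = _clamp(cond)
        par = self.parameters
        r = self.rotation
        if which == 2:
            if r == 0:
                return fam.h2inv(p, cond, par)
            if r == 180:
                return _clamp(1.0 - fam.h2inv(1.0 - p, 1.0 - cond, par))
            if r == 90:
                return _clamp(1.0 - fam.h2inv(1.0 - p, cond, par))
            return fam.h2inv(p, 1.0 - cond, par)  # 270
        if r == 0:
            return fam.h2inv(p, cond, par)
        if r == 180:
            return _clamp(1.0 - fam.h2inv(1.0 - p, 1.0 - cond, par))
        if r == 90:
            return fam.h2inv(p, 1.0 - cond, par)
        return _clamp(1.0 - fam.h2inv(1.0 - p, cond, par))  # 270

    # -- simulation -------------------------------------------------------
    def simulate(self, n: int, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw ``n`` pairs via conditional inversion; shape (n, 2)."""
        if rng is None:
            rng = np.random.default_rng(seed)
        if n == 0:
            return np.empty((0, 2))
        v = rng.uniform(size=n)
        w = rng.uniform(size=n)
        u = self.hinv(w, v, which=2)
        return np.column_stack([u, v])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "rotation": self.rotation,
            "parameters": list(self.parameters),
            "loglik": float(self.loglik),
            "n_fit": int(self.n_fit),
            "aic": float(self.aic),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BivariateCopula":
        return cls(
            family=d["family"],
            rotation=int(d.get("rotation", 0)),
            parameters=list(d.get("parameters", [])),
            loglik=float(d.get("loglik", 0.0)),
            n_fit=int(d.get("n_fit", 0)),
        )


# ---------------------------------------------------------------------------
# module-level functional API (mirrors the object methods)
# ---------------------------------------------------------------------------


def pdf(cop: BivariateCopula, u, v):
    return cop.pdf(u, v)


def hfunc(cop: BivariateCopula, u, v, which: int = 2):
    return cop.hfunc(u, v, which)


def hinv(cop: BivariateCopula, p, cond, which: int = 2):
    return cop.hinv(p, cond, which)


def par_to_tau(cop: BivariateCopula) -> float:
    return cop.tau()


def simulate_bicop(cop: BivariateCopula, n: int, seed=None) -> np.ndarray:
    return cop.simulate(n, seed=seed)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _candidates(family_set: list[str], tau_emp: float):
    """Expand family names into (family, rotation) candidates.

    One-sided families are rotated to match the sign of the empirical tau
    (0/180 for positive, 90/270 for negative dependence); two-sided families
    cover both signs unrotated.
    """
    cands = []
    for name in family_set:
        fam = FAMILIES[name]
        if name == "independence":
            continue  # always added separately
        if fam.one_sided:
            rots = (0, 180) if tau_emp >= 0 else (90, 270)
            cands.extend((name, r) for r in rots)
        else:
            cands.append((name, 0))
    return cands


def fit_bicop(
    u,
    v,
    weights=None,
    family_set: list[str] | None = None,
) -> BivariateCopula:
    """Fit each candidate family by weighted ML and select by AIC.

    Parameters are initialized by tau inversion and optimized with a
    box-constrained quasi-Newton method.  The independence copula is always a
    candidate; with fewer than 20 observations it is returned directly with a
    logged warning.  Ties on AIC break toward fewer parameters, then the
    canonical family order, then rotation.
    """
    u = _clamp(u)
    v = _clamp(v)
    if u.shape != v.shape:
        raise ValueError("u and v must have equal length")
    n = u.size
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != u.shape:
            raise ValueError("weights must align with data")
        w = w * (n / w.sum())  # normalize so sum(w) = n
    else:
        w = np.ones(n)

    indep = BivariateCopula("independence", 0, [], loglik=0.0, n_fit=n)
    if n < MIN_FIT_N:
        log.warning("fit_bicop: n=%d < %d, falling back to independence", n, MIN_FIT_N)
        return indep

    if family_set is None:
        family_set = DEFAULT_FAMILY_SET
    for name in family_set:
        if name not in FAMILIES:
            raise ValueError(f"unknown copula family {name!r}")

    tau_emp = stats.kendalltau(u, v).statistic
    if not np.isfinite(tau_emp):
        tau_emp = 0.0

    fitted = [indep]
    for name, rot in _candidates(list(family_set), tau_emp):
        fam = FAMILIES[name]
        tau_base = abs(tau_emp) if fam.one_sided else tau_emp
        x0 = np.asarray(fam.par_init(tau_base), dtype=float)
        lo = np.array([b[0] for b in fam.bounds])
        hi = np.array([b[1] for b in fam.bounds])
        x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)

        uu, vv = u, v
        if rot == 90:
            uu = 1.0 - u
        elif rot == 180:
            uu, vv = 1.0 - u, 1.0 - v
        elif rot == 270:
            vv = 1.0 - v

        def negll(par, _uu=uu, _vv=vv, _fam=fam):
            with np.errstate(all="ignore"):
                lp = _fam.logpdf(_uu, _vv, par)
            lp = np.where(np.isfinite(lp), lp, LOGPDF_FLOOR)
            return -float(np.sum(w * np.maximum(lp, LOGPDF_FLOOR)))

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    negll, x0, method="L-BFGS-B", bounds=fam.bounds,
                    options={"maxiter": 200, "ftol": 1e-10},
                )
            ll = -float(res.fun)
            if not np.isfinite(ll):
                continue
            fitted.append(
                BivariateCopula(name, rot, list(np.asarray(res.x, dtype=float)), loglik=ll, n_fit=n)
            )
        except (ValueError, FloatingPointError) as err:  # pragma: no cover - defensive
            log.warning("fit_bicop: %s rot %d failed: %s", name, rot, err)

    def sort_key(c: BivariateCopula):
        return (round(c.aic, 10), c.n_params, FAMILY_ORDER.index(c.family), c.rotation)

    return min(fitted, key=sort_key)
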