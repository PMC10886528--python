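"""Candidate outcome distributions for bounded screening scores.

Eight families are supported: four continuous (normal, log-normal, gamma,
Weibull) and four count families (Poisson, negative binomial, Conway--Maxwell--
Poisson, generalised Poisson).  Covariates always enter through a linear
predictor ``eta = X @ beta``:

* normal -- identity link on the mean,
* log-normal -- identity link on the log-scale location (``mu_log = eta``),
* gamma, Poisson, NB, GP -- log link on the mean,
* Weibull -- log link on the scale parameter,
* CMP -- log link on the rate ``lambda`` (NOT the mean; the mean-parameterised
  CMP has no tractable closed form, so coefficients are on the log-rate scale).

Each family carries at most one auxiliary (non-location) parameter:

====== =========== ======================================
family aux         admissible region
====== =========== ======================================
normal sigma       sigma > 0
lognormal sigma    sigma > 0
gamma  shape a     a > 0
weibull shape k    k > 0
poisson (none)
nb     alpha       alpha >= 0  (variance mu*(1+alpha*mu), "NB2")
cmp    nu          nu > 0      (nu < 1 overdispersed, nu > 1 underdispersed)
gp     delta       0 <= delta < 1 (non-negative-dispersion branch)
====== =========== ======================================

The generalised Poisson uses the Consul parameterisation
``P(Y=y) = theta*(theta+delta*y)^(y-1) * exp(-(theta+delta*y)) / y!`` with
``theta = mu*(1-delta)``, so its mean is ``theta/(1-delta)`` and its variance
``theta/(1-delta)^3``.  Only the overdispersed branch ``0 <= delta < 1`` is
implemented; the negative-delta branch truncates the support and is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .exceptions import DomainError, NumericalError

__all__ = [
    "FAMILY_NAMES",
    "COUNT_FAMILIES",
    "CONTINUOUS_FAMILIES",
    "POSITIVE_FAMILIES",
    "ParameterSet",
    "get_family",
    "log_density",
    "family_mean",
    "cmp_normalizer",
    "cmp_log_normalizer",
]

FAMILY_NAMES = ("normal", "lognormal", "gamma", "weibull", "poisson", "nb", "cmp", "gp")
COUNT_FAMILIES = ("poisson", "nb", "cmp", "gp")
CONTINUOUS_FAMILIES = ("normal", "lognormal", "gamma", "weibull")
#: families whose support excludes zero, hence may need a positivity shift
POSITIVE_FAMILIES = ("lognormal", "gamma", "weibull")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ParameterSet:
    """Coefficients on the link scale plus the family's auxiliary parameter.

    ``beta[0]`` is the intercept; subsequent entries follow the covariate
    order of the fitted model.  ``aux`` is None for the Poisson.
    """

    beta: np.ndarray
    aux: float | None = None
    aux_name: str | None = None

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))

    def as_vector(self) -> np.ndarray:
        if self.aux is None:
            return self.beta.copy()
        return np.append(self.beta, self.aux)


# ---------------------------------------------------------------------------
# CMP normalising constant
# ---------------------------------------------------------------------------

_CMP_MAX_TERMS = 10_000


def cmp_log_normalizer(log_lam, nu: float, tol: float = 1e-12):
    """log Z(lambda, nu), Z = sum_{j>=0} lambda^j / (j!)^nu, vectorised in lambda.

    The series is accumulated in log space.  The terms peak near
    ``j* = lambda^(1/nu)``, so summation starts with a truncation point well
    past the largest row's peak and extends until the current tail term falls
    below ``tol`` times the running sum.  Raises :class:`NumericalError` if
    10,000 terms do not suffice (possible for nu near 0 with large lambda).
    """
    log_lam = np.asarray(log_lam, dtype=float)
    scalar = log_lam.ndim == 0
    ll = np.atleast_1d(log_lam).astype(float)
    if nu <= 0:
        raise DomainError(f"CMP requires nu > 0, got nu={nu}")
    if not np.all(np.isfinite(ll)):
        raise DomainError("CMP requires finite, positive lambda")

    with np.errstate(over="ignore"):
        j_peak = float(np.exp(np.max(ll) / nu))
    if j_peak > _CMP_MAX_TERMS:
        raise NumericalError(
            f"CMP normalizer did not converge within {_CMP_MAX_TERMS} terms "
            f"(lambda up to {float(np.exp(np.max(ll))):.4g}, nu={nu})"
        )
    log_tol = np.log(tol)
    acc = np.zeros_like(ll)  # running logsumexp; the j=0 term is log(1)=0
    start = 1
    # first block reaches past the peak plus a tail allowance
    end = int(min(max(32, j_peak + 20.0 * np.sqrt(j_peak + 1.0) + 30.0), _CMP_MAX_TERMS))
    while True:
        js = np.arange(start, end + 1, dtype=float)
        terms = js[None, :] * ll[:, None] - nu * special.gammaln(js + 1.0)[None, :]
        acc = np.logaddexp(acc, special.logsumexp(terms, axis=1))
        if np.all(terms[:, -1] - acc < log_tol):
            return acc[0] if scalar else acc
        if end >= _CMP_MAX_TERMS:
            raise NumericalError(
                f"CMP normalizer did not converge within {_CMP_MAX_TERMS} terms "
                f"(lambda up to {float(np.exp(np.max(ll))):.4g}, nu={nu})"
            )
        start, end = end + 1, int(min(2 * end, _CMP_MAX_TERMS))


def cmp_normalizer(lam: float, nu: float, tol: float = 1e-12) -> float:
    """Z(lambda, nu) on the natural scale; relative error at most ``tol``."""
    if lam <= 0:
        raise DomainError(f"CMP requires lambda > 0, got lambda={lam}")
    return float(np.exp(cmp_log_normalizer(np.log(lam), nu, tol=tol)))


def _cmp_pmf_table(log_lam: float, nu: float, tol: float = 1e-12) -> np.ndarray:
    """pmf of CMP(lambda, nu) on 0..J where the truncated tail mass is < tol."""
    log_z = cmp_log_normalizer(log_lam, nu, tol=tol)
    probs = [np.exp(-log_z)]
    j = 1
    total = probs[0]
    while total < 1.0 - tol and j <= _CMP_MAX_TERMS:
        p = np.exp(j * log_lam - nu * special.gammaln(j + 1.0) - log_z)
        probs.append(p)
        total += p
        j += 1
    return np.asarray(probs)


# ---------------------------------------------------------------------------
# Family definitions
# ---------------------------------------------------------------------------


class Family:
    """Interface shared by all eight candidate families.

    Subclasses implement vectorised log-density, sampling, mean, and a
    method-of-moments starting point used to initialise ML fitting.
    """

    name: str = ""
    support: str = ""  # 'reals' | 'positive' | 'counts'
    n_aux: int = 1
    aux_name: str | None = None
    aux_transform: str | None = None  # 'log' | 'logit' | None
    has_cdf: bool = False

    # -- subclass API -------------------------------------------------------
    def loglik(self, y: np.ndarray, eta: np.ndarray, aux: float | None) -> np.ndarray:
        raise NotImplementedError

    def mean(self, eta: np.ndarray, aux: float | None) -> np.ndarray:
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, eta: np.ndarray, aux: float | None) -> np.ndarray:
        raise NotImplementedError

    def cdf(self, y: np.ndarray, eta: np.ndarray, aux: float | None) -> np.ndarray:
        raise NotImplementedError

    def mom_start(self, y: np.ndarray) -> tuple[float, float | None]:
        """(intercept on the link scale, auxiliary on the natural scale)."""
        raise NotImplementedError

    # -- shared helpers ------------------------------------------------------
    def admissible_aux(self, aux: float | None) -> bool:
        if self.n_aux == 0:
            return aux is None or aux == 0
        return aux is not None and np.isfinite(aux) and self._aux_ok(float(aux))

    def _aux_ok(self, aux: float) -> bool:
        return aux > 0

    def in_support(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(y)
        if self.support == "positive":
            ok &= y > 0
        elif self.support == "counts":
            ok &= (y >= 0) & (y == np.round(y))
        return ok

    def validate_support(self, y: np.ndarray) -> None:
        ok = self.in_support(np.asarray(y, dtype=float))
        if not np.all(ok):
            bad = np.flatnonzero(~ok)
            raise DomainError(
                f"{self.name}: {bad.size} value(s) outside the {self.support} support "
                f"(first offender index {bad[0]}, value {np.asarray(y).ravel()[bad[0]]})"
            )


class Normal(Family):
    name = "normal"
    support = "reals"
    aux_name = "sigma"
    aux_transform = "log"
    has_cdf = True

    def loglik(self, y, eta, aux):
        s2 = aux * aux
        return -0.5 * (_LOG_2PI + np.log(s2) + (y - eta) ** 2 / s2)

    def mean(self, eta, aux):
        return np.asarray(eta, dtype=float)

    def sample(self, rng, eta, aux):
        return rng.normal(eta, aux)

    def cdf(self, y, eta, aux):
        return stats.norm.cdf(y, loc=eta, scale=aux)

    def mom_start(self, y):
        return float(np.mean(y)), max(float(np.std(y)), 1e-6)


class LogNormal(Family):
    name = "lognormal"
    support = "positive"
    aux_name = "sigma"
    aux_transform = "log"
    has_cdf = True

    def loglik(self, y, eta, aux):
        ly = np.log(y)
        s2 = aux * aux
        return -ly - 0.5 * (_LOG_2PI + np.log(s2) + (ly - eta) ** 2 / s2)

    def mean(self, eta, aux):
        return np.exp(eta + 0.5 * aux * aux)

    def sample(self, rng, eta, aux):
        return rng.lognormal(eta, aux)

    def cdf(self, y, eta, aux):
        return stats.lognorm.cdf(y, aux, scale=np.exp(eta))

    def mom_start(self, y):
        ly = np.log(y)
        return float(np.mean(ly)), max(float(np.std(ly)), 1e-6)


class Gamma(Family):
    name = "gamma"
    support = "positive"
    aux_name = "shape"
    aux_transform = "log"
    has_cdf = True

    def loglik(self, y, eta, aux):
        # mean mu = exp(eta), shape a, scale = mu/a
        a = aux
        log_scale = eta - np.log(a)
        return (a - 1.0) * np.log(y) - y * np.exp(-log_scale) - a * log_scale - special.gammaln(a)

    def mean(self, eta, aux):
        return np.exp(eta)

    def sample(self, rng, eta, aux):
        return rng.gamma(aux, np.exp(eta) / aux)

    def cdf(self, y, eta, aux):
        return stats.gamma.cdf(y, a=aux, scale=np.exp(eta) / aux)

    def mom_start(self, y):
        m, v = float(np.mean(y)), float(np.var(y))
        a = m * m / max(v, 1e-12)
        return np.log(m), float(np.clip(a, 1e-3, 1e6))


class Weibull(Family):
    name = "weibull"
    support = "positive"
    aux_name = "shape"
    aux_transform = "log"
    has_cdf = True

    def loglik(self, y, eta, aux):
        k = aux
        z = k * (np.log(y) - eta)  # = log((y/scale)^k)
        return np.log(k) - eta + (1.0 - 1.0 / k) * z - np.exp(np.minimum(z, 700.0))

    def mean(self, eta, aux):
        return np.exp(eta) * special.gamma(1.0 + 1.0 / aux)

    def sample(self, rng, eta, aux):
        return np.exp(eta) * rng.weibull(aux, size=np.shape(eta) if np.ndim(eta) else None)

    def cdf(self, y, eta, aux):
        return stats.weibull_min.cdf(y, aux, scale=np.exp(eta))

    def mom_start(self, y):
        m, s = float(np.mean(y)), float(np.std(y))
        cv = max(s / m, 1e-3)
        k = float(np.clip(cv ** -1.086, 0.05, 50.0))  # standard CV approximation
        scale = m / special.gamma(1.0 + 1.0 / k)
        return float(np.log(scale)), k


class Poisson(Family):
    name = "poisson"
    support = "counts"
    n_aux = 0
    aux_name = None
    aux_transform = None

    def loglik(self, y, eta, aux=None):
        return y * eta - np.exp(eta) - special.gammaln(y + 1.0)

    def mean(self, eta, aux=None):
        return np.exp(eta)

    def sample(self, rng, eta, aux=None):
        return rng.poisson(np.exp(eta))

    def mom_start(self, y):
        return float(np.log(max(np.mean(y), 1e-8))), None


class NegativeBinomial(Family):
    """NB2: mean mu = exp(eta), variance mu*(1 + alpha*mu); alpha >= 0 nests Poisson."""

    name = "nb"
    support = "counts"
    aux_name = "alpha"
    aux_transform = "log"

    def _aux_ok(self, aux):
        return aux >= 0

    def loglik(self, y, eta, aux):
        if aux < 1e-14:
            return Poisson().loglik(y, eta)
        r = 1.0 / aux
        mu = np.exp(eta)
        y_arr = np.atleast_1d(np.asarray(y, dtype=float))
        # lgamma(y+r) - lgamma(r) = sum_{i<y} log(r+i); the direct gammaln
        # difference cancels catastrophically for large r (alpha -> 0), while
        # this exact cumulative sum stays accurate for the small integer
        # outcomes the package works with.
        y_max = int(y_arr.max())
        cum = np.concatenate(([0.0], np.cumsum(np.log(r + np.arange(y_max)))))
        ratio = cum[y_arr.astype(int)]
        out = (
            ratio
            - special.gammaln(y_arr + 1.0)
            - r * np.log1p(mu / r)
            + y_arr * (eta - np.log(r + mu))
        )
        return out if np.ndim(y) or np.ndim(eta) else float(out[0])

    def mean(self, eta, aux):
        return np.exp(eta)

    def sample(self, rng, eta, aux):
        mu = np.exp(eta)
        if aux < 1e-12:
            return rng.poisson(mu)
        r = 1.0 / aux
        lam = rng.gamma(r, mu / r)  # gamma-Poisson mixture
        return rng.poisson(lam)

    def mom_start(self, y):
        m, v = float(np.mean(y)), float(np.var(y))
        alpha = max((v - m) / max(m * m, 1e-12), 1e-3)
        return float(np.log(max(m, 1e-8))), float(min(alpha, 100.0))


class ConwayMaxwellPoisson(Family):
    """CMP(lambda, nu) with pmf lambda^y / (y!)^nu / Z(lambda, nu).

    Covariates act on log(lambda); nu = 1 recovers the Poisson exactly.
    """

    name = "cmp"
    support = "counts"
    aux_name = "nu"
    aux_transform = "log"

    def loglik(self, y, eta, aux):
        eta = np.asarray(eta, dtype=float)
        if eta.ndim == 0 or np.all(eta == eta.flat[0]):
            log_z = cmp_log_normalizer(np.float64(eta.flat[0] if eta.ndim else eta), aux)
        else:
            log_z = cmp_log_normalizer(eta, aux)
        return y * eta - aux * special.gammaln(y + 1.0) - log_z

    def mean(self, eta, aux):
        eta = np.atleast_1d(np.asarray(eta, dtype=float))
        out = np.empty(eta.shape)
        cache: dict[float, float] = {}
        for i, e in enumerate(eta):
            key = float(e)
            if key not in cache:
                pmf = _cmp_pmf_table(key, aux)
                cache[key] = float(np.sum(np.arange(pmf.size) * pmf))
            out[i] = cache[key]
        return out if out.size > 1 else out[0]

    def sample(self, rng, eta, aux):
        eta = np.atleast_1d(np.asarray(eta, dtype=float))
        out = np.empty(eta.shape, dtype=np.int64)
        # group identical rates so intercept-only simulation builds one table
        uniq, inv = np.unique(eta, return_inverse=True)
        for u_idx, e in enumerate(uniq):
            pmf = _cmp_pmf_table(float(e), aux, tol=1e-12)
            cdf = np.cumsum(pmf)
            rows = np.flatnonzero(inv == u_idx)
            u = rng.random(rows.size)
            out[rows] = np.searchsorted(cdf, u * cdf[-1], side="right")
        return out

    def mom_start(self, y):
        return float(np.log(max(np.mean(y), 1e-8))), 1.0


class GeneralizedPoisson(Family):
    """Consul's generalised Poisson, non-negative-dispersion branch.

    mean = theta/(1-delta) = exp(eta); variance = theta/(1-delta)^3.
    delta = 0 recovers the Poisson exactly.
    """

    name = "gp"
    support = "counts"
    aux_name = "delta"
    aux_transform = "logit"

    def _aux_ok(self, aux):
        return 0 <= aux < 1

    def loglik(self, y, eta, aux):
        delta = aux
        theta = np.exp(eta) * (1.0 - delta)
        rate = theta + delta * y
        return np.log(theta) + (y - 1.0) * np.log(rate) - rate - special.gammaln(y + 1.0)

    def mean(self, eta, aux):
        return np.exp(eta)

    def sample(self, rng, eta, aux):
        # Exact draw via the branching (Galton-Watson) representation:
        # ancestors ~ Poisson(theta); each individual spawns Poisson(delta)
        # offspring; the total progeny is GP(theta, delta).
        theta = np.exp(np.asarray(eta, dtype=float)) * (1.0 - aux)
        total = rng.poisson(theta)
        gen = total.copy() if np.ndim(total) else np.atleast_1d(total).copy()
        total = np.atleast_1d(total).astype(np.int64)
        gen = np.atleast_1d(gen).astype(np.int64)
        if aux > 0:
            while np.any(gen > 0):
                gen = rng.poisson(aux * gen)
                total += gen
        return total if np.ndim(eta) else total[0]

    def mom_start(self, y):
        m, v = float(np.mean(y)), float(np.var(y))
        if v > m > 0:
            delta = float(np.clip(1.0 - np.sqrt(m / v), 1e-4, 0.95))
        else:
            delta = 1e-4
        return float(np.log(max(m, 1e-8))), delta


_REGISTRY: dict[str, Family] = {
    f.name: f
    for f in (
        Normal(),
        LogNormal(),
        Gamma(),
        Weibull(),
        Poisson(),
        NegativeBinomial(),
        ConwayMaxwellPoisson(),
        GeneralizedPoisson(),
    )
}


def get_family(name: str) -> Family:
    """Look up a family by name; raises DomainError for unknown names."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise DomainError(
            f"unknown family {name!r}; choose from {', '.join(FAMILY_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def _eta_from(params: ParameterSet, x=None) -> np.ndarray:
    beta = params.beta
    if x is None:
        return np.asarray(beta[0], dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != beta.size:
        raise DomainError(
            f"design row has {x.shape[1]} columns but beta has {beta.size} entries"
        )
    return x @ beta


def log_density(family: str | Family, y, params: ParameterSet, x=None):
    """Log density/mass of ``family`` at ``y`` given parameters and optional covariates.

    ``x`` is a design row (or matrix) including the intercept column; when
    omitted, ``params.beta[0]`` alone defines the linear predictor.
    """
    fam = get_family(family) if isinstance(family, str) else family
    y_arr = np.asarray(y, dtype=float)
    fam.validate_support(y_arr)
    if not fam.admissible_aux(params.aux if fam.n_aux else None):
        raise DomainError(
            f"{fam.name}: inadmissible auxiliary parameter {fam.aux_name}={params.aux}"
        )
    eta = _eta_from(params, x)
    out = fam.loglik(y_arr, eta, params.aux)
    return float(out) if np.ndim(y) == 0 and np.ndim(out) <= 1 and np.size(out) == 1 else out


def family_mean(family: str | Family, params: ParameterSet, x=None):
    """Model-implied mean outcome, closed form where available (CMP numeric)."""
    fam = get_family(family) if isinstance(family, str) else family
    if not fam.admissible_aux(params.aux if fam.n_aux else None):
        raise DomainError(
            f"{fam.name}: inadmissible auxiliary parameter {fam.aux_name}={params.aux}"
        )
    eta = _eta_from(params, x)
    out = fam.mean(eta, params.aux)
    return float(out) if np.size(out) == 1 else out
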