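"""Maximum-likelihood fitting of the candidate families.

A :class:`ModelSpec` names the family, the outcome column, the score
orientation (original vs inverse), and the covariates (any subset of age,
sex, education; empty means intercept-only).  Sex enters as a female
indicator (female = 1, male = 0) and age/education in natural units (years).

Optimisation happens on an unconstrained scale: regression coefficients as
they are, positive auxiliary parameters through log, and the generalised-
Poisson dispersion through logit.  The starting point is a method-of-moments
estimate, optionally followed by jittered restarts; the best finite optimum
is kept.  Standard errors come from the inverse observed information
(numerical Hessian of the negative log-likelihood at the optimum), mapped to
the natural scale by the delta method.  When the observed information is not
positive definite the standard errors are reported as missing rather than
being patched with a pseudo-inverse — such failures are informative about
the model/data combination and should stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .exceptions import ConfigurationError, DataError
from .families import Family, ParameterSet, get_family
from .transforms import DEFAULT_SHIFT, ScoreVector, invert_scores, shift_for_positive_support

__all__ = ["ModelSpec", "FitResult", "fit_model", "design_matrix", "prepare_outcome"]

VALID_COVARIATES = ("age", "sex", "education")
GRAD_TOL = 1e-5  # sup-norm of the gradient of the mean log-likelihood
_BIG = 1e10


@dataclass(frozen=True)
class ModelSpec:
    """family x scenario x orientation definition of one model to fit."""

    family: str
    outcome: str = "vcat"
    orientation: str = "original"
    covariates: tuple[str, ...] = ()
    max_score: int = 30
    shift: float = DEFAULT_SHIFT  # positivity shift applied if zeros meet a positive family

    def __post_init__(self):
        get_family(self.family)  # raises for unknown names
        if self.orientation not in ("original", "inverse"):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        cov = tuple(self.covariates)
        if len(set(cov)) != len(cov):
            raise ConfigurationError(f"duplicate covariates in {cov}")
        unknown = set(cov) - set(VALID_COVARIATES)
        if unknown:
            raise ConfigurationError(f"unknown covariates {sorted(unknown)}")
        object.__setattr__(self, "covariates", cov)

    @property
    def scenario(self) -> str:
        return "with_covariates" if self.covariates else "intercept_only"


@dataclass
class FitResult:
    """ML estimates with convergence diagnostics and the GOF building blocks."""

    spec: ModelSpec
    params: ParameterSet
    standard_errors: np.ndarray  # natural scale, aligned with params.as_vector(); NaN if unavailable
    n: int
    k: int
    minus2LL: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        names = ["intercept"] + list(self.spec.covariates)
        fam = get_family(self.spec.family)
        if fam.n_aux:
            names.append(fam.aux_name)
        return names

    @property
    def shift(self) -> float:
        return self.diagnostics.get("shift", 0.0)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .synthetic import cohort_to_frame  # local import to avoid a cycle

    return cohort_to_frame(records)


def design_matrix(frame: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    """Intercept column plus the requested covariates; sex coded female=1."""
    cols = [np.ones(len(frame))]
    for c in covariates:
        if c == "sex":
            cols.append((frame["sex"].astype(str) == "female").to_numpy(dtype=float))
        else:
            cols.append(frame[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def prepare_outcome(frame: pd.DataFrame, spec: ModelSpec) -> ScoreVector:
    """Extract the outcome, apply the orientation and any positivity shift."""
    if spec.outcome not in frame.columns:
        raise ConfigurationError(f"outcome {spec.outcome!r} not found in data")
    sv = ScoreVector(frame[spec.outcome].to_numpy(dtype=float), max_score=spec.max_score)
    if spec.orientation == "inverse":
        sv = invert_scores(sv)
    return shift_for_positive_support(sv, spec.family, shift=spec.shift)


# ---------------------------------------------------------------------------
# Parameter transforms (unconstrained optimisation scale <-> natural scale)
# ---------------------------------------------------------------------------


def _aux_to_natural(fam: Family, t: float) -> float:
    if fam.aux_transform == "log":
        return float(np.exp(t))
    if fam.aux_transform == "logit":
        return float(special.expit(t))
    return t


def _aux_to_unconstrained(fam: Family, a: float) -> float:
    if fam.aux_transform == "log":
        return float(np.log(max(a, 1e-10)))
    if fam.aux_transform == "logit":
        return float(special.logit(np.clip(a, 1e-8, 1 - 1e-8)))
    return a


def _aux_jacobian(fam: Family, t: float) -> float:
    """d(natural)/d(unconstrained) at t, for the delta method."""
    if fam.aux_transform == "log":
        return float(np.exp(t))
    if fam.aux_transform == "logit":
        p = special.expit(t)
        return float(p * (1 - p))
    return 1.0


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_model(
    records,
    spec: ModelSpec,
    *,
    n_restarts: int = 5,
    compute_se: bool = True,
    start: ParameterSet | None = None,
    random_state: int = 0,
) -> FitResult:
    """Fit one model by maximum likelihood.

    Parameters
    ----------
    records
        A cohort DataFrame (columns id, age, sex, education, plus score
        columns) or a list of :class:`SubjectRecord`.
    spec
        What to fit: family, outcome, orientation, covariates.
    n_restarts
        Number of jittered restarts around the method-of-moments start; the
        best finite optimum across all starts is kept.
    compute_se
        When False, skips the observed-information computation (standard
        errors come back as NaN) — used by the bootstrap where only point
        estimates and GOF values are needed.
    start
        Optional warm start (natural scale) overriding the method-of-moments
        start, e.g. the base-data estimates during bootstrap resampling.
    """
    frame = _as_frame(records)
    fam = get_family(spec.family)
    sv = prepare_outcome(frame, spec)
    y = sv.values
    X = design_matrix(frame, spec.covariates)
    n, p = X.shape
    k = p + fam.n_aux

    if n < k + 1:
        raise DataError(f"{n} records cannot identify {k} parameters")
    if np.all(y == y[0]):
        raise DataError("degenerate data: all outcome values identical")
    fam.validate_support(y)

    # Standardise the covariate columns for optimisation (better-conditioned
    # Hessian); coefficients are mapped back to natural units afterwards via
    # the linear map beta_natural = A @ beta_scaled.
    mu_x = np.zeros(p)
    sd_x = np.ones(p)
    if p > 1:
        mu_x[1:] = X[:, 1:].mean(axis=0)
        sd = X[:, 1:].std(axis=0)
        sd_x[1:] = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu_x) / sd_x
    Xs[:, 0] = 1.0
    A = np.eye(p)
    A[0, 1:] = -mu_x[1:] / sd_x[1:]
    for j in range(1, p):
        A[j, j] = 1.0 / sd_x[j]

    # objective: mean negative log-likelihood on the unconstrained, scaled scale
    def nll(t: np.ndarray) -> float:
        beta = t[:p]
        aux = _aux_to_natural(fam, t[p]) if fam.n_aux else None
        eta = Xs @ beta if p > 1 else np.full(n, beta[0])
        try:
            with np.errstate(all="ignore"):
                val = -float(np.mean(fam.loglik(y, eta, aux)))
        except (ArithmeticError, FloatingPointError):
            return _BIG
        return val if np.isfinite(val) else _BIG

    eta0, aux0 = fam.mom_start(y)
    t_mom = np.zeros(k)
    t_mom[0] = eta0
    if fam.n_aux:
        t_mom[p] = _aux_to_unconstrained(fam, aux0)
    if start is not None:
        # warm start given in natural units: invert the standardisation map
        t0 = np.zeros(k)
        b_nat = np.zeros(p)
        b_nat[: start.beta.size] = start.beta
        t0[1:p] = b_nat[1:] * sd_x[1:]
        t0[0] = b_nat[0] + b_nat[1:] @ mu_x[1:]
        if fam.n_aux:
            t0[p] = _aux_to_unconstrained(fam, start.aux)
    else:
        t0 = t_mom

    # for some family/scenario pairs the moment start already solves the
    # likelihood equations (normal and Poisson intercept-only have closed-form
    # MLEs); accept it outright when its gradient clears the tolerance
    g_mom = approx_fprime(t_mom, nll, centered=True)
    if np.max(np.abs(g_mom)) < 0.1 * GRAD_TOL and nll(t_mom) < _BIG:
        best_x, best_f, best_nit, best_msg = t_mom, float(nll(t_mom)), 0, "moment start optimal"
    else:
        rng = np.random.default_rng(random_state)
        starts = [t0] + [t0 + rng.normal(0.0, 0.3, size=k) for _ in range(n_restarts)]
        if start is not None:
            starts.append(t_mom)
        if spec.family in ("nb", "gp"):
            # these families nest the Poisson at the lower boundary of their
            # dispersion parameter; underdispersed data push the MLE there,
            # which plain quasi-Newton runs can miss from an interior start
            t_b = t0.copy()
            t_b[p] = -15.0
            starts.append(t_b)

        best_x, best_f, best_nit, best_msg = None, np.inf, 0, ""
        for s in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(nll, s, method="BFGS",
                                        options={"gtol": 1e-7, "maxiter": 500})
            if np.isfinite(res.fun) and res.fun < _BIG and res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
                best_nit, best_msg = int(res.nit), str(res.message)

    if best_x is None:
        params = ParameterSet(A @ t0[:p], _aux_to_natural(fam, t0[p]) if fam.n_aux else None,
                              fam.aux_name)
        return FitResult(spec, params, np.full(k, np.nan), n, k, float("nan"), False,
                         {"message": "no finite optimum across starts", "shift": sv.shift})

    # Newton polish: push the gradient below tolerance where BFGS stopped short
    t_hat = best_x
    grad = approx_fprime(t_hat, nll, centered=True)
    grad_norm = float(np.max(np.abs(grad)))
    hess_s = None
    for _ in range(10):
        if grad_norm < 0.1 * GRAD_TOL:
            break
        hess_s = approx_hess(t_hat, nll)
        try:
            step = np.linalg.solve(hess_s, grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
            cand = t_hat - damp * step
            f_cand = nll(cand)
            if f_cand <= best_f + 1e-12:
                g_cand = approx_fprime(cand, nll, centered=True)
                if np.max(np.abs(g_cand)) < grad_norm:
                    t_hat, best_f = cand, f_cand
                    grad, grad_norm = g_cand, float(np.max(np.abs(g_cand)))
                    improved = True
                break
        if not improved:
            break

    beta_hat = A @ t_hat[:p]
    aux_hat = _aux_to_natural(fam, t_hat[p]) if fam.n_aux else None
    params = ParameterSet(beta_hat, aux_hat, fam.aux_name)

    eta_hat = X @ beta_hat if p > 1 else np.full(n, beta_hat[0])
    minus2ll = -2.0 * float(np.sum(fam.loglik(y, eta_hat, aux_hat)))

    se = np.full(k, np.nan)
    info_pd = None
    if compute_se:
        if hess_s is None:
            hess_s = approx_hess(t_hat, nll)
        hess = hess_s * n  # observed information of the total NLL (scaled space)
        try:
            np.linalg.cholesky(hess)
            info_pd = True
            cov_t = np.linalg.inv(hess)
            jac = np.zeros((k, k))
            jac[:p, :p] = A
            if fam.n_aux:
                jac[p, p] = _aux_jacobian(fam, t_hat[p])
            cov_nat = jac @ cov_t @ jac.T
            se = np.sqrt(np.clip(np.diag(cov_nat), 0, None))
        except np.linalg.LinAlgError:
            info_pd = False
            warnings.warn(
                f"{spec.family}: observed information not positive definite at the "
                "optimum; standard errors reported as missing",
                stacklevel=2,
            )

    converged = grad_norm < GRAD_TOL and (info_pd is not False)
    diagnostics = {
        "grad_norm": grad_norm,
        "info_positive_definite": info_pd,
        "n_iterations": best_nit,
        "shift": sv.shift,
        "start_loglik": -nll(t0) * n,
        "message": best_msg,
    }
    return FitResult(spec, params, se, n, k, minus2ll, bool(converged), diagnostics)
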