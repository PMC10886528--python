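"""Goodness-of-fit statistics, model ranking, and predicted score distributions.

AIC and BIC follow the all-free-parameters counting convention: ``k`` is the
number of regression coefficients plus auxiliary parameters, so an
intercept-only Poisson has k = 1, an intercept-only normal k = 2, and any
two-parameter family with three covariates k = 5.  Lower values of −2LL, AIC
and BIC indicate better fit; models that failed to converge rank last no
matter what their statistics say.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ComparisonError, DataError
from .families import COUNT_FAMILIES, get_family
from .fitting import FitResult, design_matrix, prepare_outcome, _as_frame

__all__ = ["GOFRow", "PredictedDistribution", "goodness_of_fit", "rank_models",
           "predicted_score_distribution"]


@dataclass(frozen=True)
class GOFRow:
    """One family x scenario x orientation line of a comparison grid."""

    family: str
    scenario: str
    orientation: str
    outcome: str
    n: int
    k: int
    minus2LL: float
    aic: float
    bic: float
    converged: bool
    shifted: bool = False


@dataclass
class PredictedDistribution:
    """Observed vs model-implied expected frequency at each integer score."""

    scores: np.ndarray  # 0..max_score
    expected: np.ndarray
    observed: np.ndarray
    spillover: float  # expected mass beyond the score range (count families)
    family: str
    scenario: str
    orientation: str


def goodness_of_fit(fit: FitResult) -> GOFRow:
    """AIC = −2LL + 2k and BIC = −2LL + k·ln(n) from a fit."""
    if fit.n < 1 or fit.k < 0:
        raise DataError(f"cannot score a fit with n={fit.n}, k={fit.k}")
    m2 = fit.minus2LL
    if np.isfinite(m2):
        aic = m2 + 2.0 * fit.k
        bic = m2 + fit.k * np.log(fit.n)
    else:
        aic = bic = float("nan")  # non-comparable row; rank_models puts it last
    return GOFRow(
        family=fit.spec.family,
        scenario=fit.spec.scenario,
        orientation=fit.spec.orientation,
        outcome=fit.spec.outcome,
        n=fit.n,
        k=fit.k,
        minus2LL=m2,
        aic=aic,
        bic=bic,
        converged=fit.converged,
        shifted=fit.shift != 0,
    )


def rank_models(rows: list[GOFRow], criterion: str = "aic") -> list[GOFRow]:
    """Sort comparison rows, best (lowest criterion) first.

    Rows must share n, outcome, orientation and scenario — information
    criteria are not comparable across datasets.  Non-converged or
    non-finite rows go last; ties break toward fewer parameters, then by
    family name.
    """
    if criterion not in ("minus2LL", "aic", "bic"):
        raise ComparisonError(f"unknown criterion {criterion!r}")
    if not rows:
        return []
    ref = rows[0]
    for r in rows[1:]:
        if (r.n, r.outcome, r.orientation, r.scenario) != (
            ref.n, ref.outcome, ref.orientation, ref.scenario,
        ):
            raise ComparisonError(
                "rows are not comparable: n/outcome/orientation/scenario differ "
                f"({r.family} vs {ref.family})"
            )

    def key(r: GOFRow):
        val = getattr(r, criterion)
        bad = (not r.converged) or not np.isfinite(val)
        return (bad, float("inf") if not np.isfinite(val) else val, r.k, r.family)

    return sorted(rows, key=key)


def predicted_score_distribution(fit: FitResult, records) -> PredictedDistribution:
    """Model-implied expected counts on the integer score grid 0..max_score.

    Count families accumulate exact per-record probabilities
    ``sum_i P(Y_i = s | x_i)``; probability mass above the maximum score is
    reported as ``spillover``.  Continuous families integrate the density
    over (s−0.5, s+0.5), with the boundary bins extended to (−inf, 0.5] and
    [max−0.5, +inf) so total mass is conserved.  Any positivity shift used in
    fitting is applied to the evaluation grid.
    """
    if not fit.converged:
        raise DataError(
            f"refusing to predict from a non-converged {fit.spec.family} fit; "
            "inspect FitResult.diagnostics"
        )
    frame = _as_frame(records)
    spec = fit.spec
    fam = get_family(spec.family)
    sv = prepare_outcome(frame, spec)
    X = design_matrix(frame, spec.covariates)
    n, p = X.shape
    beta = fit.params.beta
    aux = fit.params.aux
    eta = X @ beta if p > 1 else np.full(n, beta[0])

    grid = np.arange(spec.max_score + 1)
    y_grid = grid + fit.shift  # evaluate on the (possibly shifted) fitting scale

    if spec.family in COUNT_FAMILIES:
        # pmf matrix (n x 31); vectorised over the grid
        probs = np.empty((n, grid.size))
        for s_idx, s in enumerate(y_grid):
            probs[:, s_idx] = np.exp(fam.loglik(float(s), eta, aux))
        expected = probs.sum(axis=0)
        spillover = float(n - expected.sum())
    else:
        edges = y_grid + 0.5
        upper = np.empty((n, grid.size))
        for s_idx, e in enumerate(edges):
            upper[:, s_idx] = fam.cdf(float(e), eta, aux)
        lower = np.empty_like(upper)
        lower[:, 0] = 0.0  # bottom bin extends to -inf (or 0 for positive support)
        lower[:, 1:] = upper[:, :-1]
        upper[:, -1] = 1.0  # top bin extends to +inf
        expected = (upper - lower).sum(axis=0)
        spillover = float(n - expected.sum())

    observed = np.bincount(
        np.round(sv.values - sv.shift).astype(int), minlength=grid.size
    )[: grid.size].astype(float)

    return PredictedDistribution(
        scores=grid,
        expected=expected,
        observed=observed,
        spillover=spillover,
        family=spec.family,
        scenario=spec.scenario,
        orientation=spec.orientation,
    )
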