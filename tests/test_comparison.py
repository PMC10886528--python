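"""Information criteria, model ranking, and predicted score distributions."""

import dataclasses

import numpy as np
import pytest

from skewfit import (
    ComparisonError,
    DataError,
    GOFRow,
    ModelSpec,
    ParameterSet,
    fit_model,
    goodness_of_fit,
    predicted_score_distribution,
    rank_models,
    simulate_from_family,
)
from skewfit.fitting import FitResult
from tests.conftest import frame_from_values


def _row(family="normal", minus2LL=100.0, k=2, n=883, converged=True, **kw):
    aic = minus2LL + 2 * k
    bic = minus2LL + k * np.log(n)
    base = dict(family=family, scenario="intercept_only", orientation="original",
                outcome="vcat", n=n, k=k, minus2LL=minus2LL, aic=aic, bic=bic,
                converged=converged)
    base.update(kw)
    return GOFRow(**base)


def _fake_fit(minus2LL, k, n, family="normal"):
    spec = ModelSpec(family)
    beta = np.zeros(max(k - 1, 1))
    return FitResult(spec, ParameterSet(beta[:1], 1.0 if k > 1 else None), np.full(k, np.nan),
                     n, k, minus2LL, True, {"shift": 0.0})


class TestGoodnessOfFit:
    @pytest.mark.parametrize(
        "minus2LL,k,aic,bic",
        [
            (5170.6, 2, 5174.6, 5184.2),   # two-parameter family, intercept-only
            (5279.9, 1, 5281.9, 5286.7),   # one-parameter family, intercept-only
            (4916.8, 5, 4926.8, 4950.7),   # two-parameter family + 3 covariates
        ],
    )
    def test_identities_on_reference_rows(self, minus2LL, k, aic, bic):
        row = goodness_of_fit(_fake_fit(minus2LL, k, 883))
        assert round(row.aic, 1) == aic
        assert round(row.bic, 1) == bic

    def test_zero_parameter_identity(self):
        row = goodness_of_fit(_fake_fit(123.4, 0, 50))
        assert row.aic == 123.4
        assert row.bic == 123.4

    def test_identities_hold_for_real_fits(self, small_frame):
        for family, orientation in [("poisson", "inverse"), ("weibull", "original")]:
            fit = fit_model(small_frame, ModelSpec(family, "vcat", orientation,
                                                   ("age", "sex", "education")))
            row = goodness_of_fit(fit)
            assert row.aic == pytest.approx(row.minus2LL + 2 * row.k, rel=1e-12)
            assert row.bic == pytest.approx(row.minus2LL + row.k * np.log(row.n), rel=1e-12)

    def test_k_counts_all_free_parameters(self, small_frame):
        assert fit_model(small_frame, ModelSpec("poisson", "vcat", "inverse")).k == 1
        assert fit_model(small_frame, ModelSpec("normal", "vcat")).k == 2
        covs = ("age", "sex", "education")
        assert fit_model(small_frame, ModelSpec("poisson", "vcat", "inverse", covs)).k == 4
        assert fit_model(small_frame, ModelSpec("weibull", "vcat", covariates=covs)).k == 5

    def test_nonfinite_minus2ll_propagates(self):
        row = goodness_of_fit(_fake_fit(float("nan"), 2, 100))
        assert np.isnan(row.aic) and np.isnan(row.bic)


class TestRankModels:
    def test_lower_aic_wins(self):
        rows = [_row("poisson", 5279.9, 1), _row("weibull", 4992.9, 2),
                _row("normal", 5170.6, 2)]
        ranked = rank_models(rows, "aic")
        assert [r.family for r in ranked] == ["weibull", "normal", "poisson"]

    def test_single_row(self):
        rows = [_row()]
        assert rank_models(rows) == rows

    def test_tie_breaks_toward_fewer_parameters(self):
        a = _row("normal", 100.0, 2, aic=110.0)
        b = _row("poisson", 100.0, 1, aic=110.0)
        assert rank_models([a, b], "aic")[0].family == "poisson"

    def test_nonconverged_rank_last(self):
        good = _row("normal", 200.0, 2)
        bad = _row("weibull", 100.0, 2, converged=False)
        assert rank_models([good, bad], "minus2LL")[0].family == "normal"

    def test_mixed_n_rejected(self):
        with pytest.raises(ComparisonError):
            rank_models([_row(n=883), _row(family="gamma", n=100)])

    def test_ordering_invariant_to_constant_shift(self):
        rows = [_row("a" + str(i), 100.0 + 7 * i, 2) for i in range(4)]
        shifted = [dataclasses.replace(r, minus2LL=r.minus2LL + 55.0, aic=r.aic + 55.0)
                   for r in rows]
        assert ([r.family for r in rank_models(rows, "aic")]
                == [r.family for r in rank_models(shifted, "aic")])


class TestPredictedDistribution:
    def test_poisson_closed_form_at_zero(self):
        y = np.array([1, 2, 3, 0, 2, 4, 1, 2, 3, 2], dtype=float)
        fit = fit_model(frame_from_values(y), ModelSpec("poisson"))
        pred = predicted_score_distribution(fit, frame_from_values(y))
        mu = np.exp(fit.params.beta[0])
        assert pred.expected[0] == pytest.approx(len(y) * np.exp(-mu), rel=1e-8)

    @pytest.mark.parametrize("family,orientation", [
        ("poisson", "inverse"), ("gp", "inverse"), ("normal", "original"),
        ("weibull", "original"), ("gamma", "inverse"),
    ])
    def test_mass_conservation(self, small_frame, family, orientation):
        fit = fit_model(small_frame, ModelSpec(family, "vcat", orientation))
        pred = predicted_score_distribution(fit, small_frame)
        assert pred.expected.sum() + pred.spillover == pytest.approx(fit.n, abs=1e-6)
        assert pred.observed.sum() == fit.n

    def test_nonconverged_fit_refused(self, small_frame):
        fit = fit_model(small_frame, ModelSpec("normal", "vcat"))
        fit.converged = False
        with pytest.raises(DataError, match="non-converged"):
            predicted_score_distribution(fit, small_frame)

    def test_overdispersed_truth_favors_gp_over_poisson(self):
        # data drawn from GP(delta=0.3): the GP fit should track the observed
        # histogram more closely than the equidispersed Poisson fit
        draws = simulate_from_family("gp", ParameterSet([np.log(5.0)], 0.3), n=883, seed=21)
        draws = np.clip(draws, 0, 30)
        fr = frame_from_values(30 - draws)  # store as original scores
        def chi2(family):
            fit = fit_model(fr, ModelSpec(family, "vcat", "inverse"))
            pred = predicted_score_distribution(fit, fr)
            e = np.maximum(pred.expected, 1e-9)
            return float(np.sum((pred.observed - e) ** 2 / e))
        assert chi2("gp") < chi2("poisson")
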