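"""Association tables and the full comparison pipeline.

The association table reports covariate effects (age, female gender,
education) for a fitted model, as Wald rows (beta +/- 1.96*SE with a
standard-normal two-sided p-value) and, when a bootstrap result is supplied,
percentile rows with sign-crossing p-values.

Sign convention: coefficients act on the link scale of the fitted
orientation.  On the inverse (error-count) scale a *negative* education
coefficient means fewer years of education go with more errors, i.e. worse
cognition — the direction clinicians expect.

``run_comparison`` drives the whole analysis: every requested outcome x
orientation x scenario x family combination is fitted, scored, and turned
into a predicted score distribution; the AIC-best converged covariate model
per outcome/orientation yields the association table; individual model
failures are recorded as non-converged rows and never abort the run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .bootstrap import BootstrapResult, bootstrap_fit
from .comparison import GOFRow, goodness_of_fit, predicted_score_distribution, rank_models
from .exceptions import ConfigurationError, DataError, SkewfitError
from .families import FAMILY_NAMES
from .fitting import FitResult, ModelSpec, fit_model
from .synthetic import CohortConfig, generate_cohort, cohort_to_frame, read_cohort_csv

__all__ = ["AssociationRow", "PipelineConfig", "ReportBundle",
           "association_table", "run_comparison"]

_VARIABLE_LABELS = {"age": "age", "sex": "female_gender", "education": "education"}


@dataclass(frozen=True)
class AssociationRow:
    variable: str
    beta: float
    ci_lower: float
    ci_upper: float
    p_value: float
    method: str  # 'wald' | 'bootstrap_percentile'


def association_table(fit: FitResult, boot: BootstrapResult | None = None) -> list[AssociationRow]:
    """Covariate-effect rows for a converged model with covariates."""
    if not fit.spec.covariates:
        raise ConfigurationError("intercept-only fits have no associations to report")
    if not fit.converged:
        raise DataError("refusing to report associations from a non-converged fit")
    rows: list[AssociationRow] = []
    names = fit.param_names
    for j, cov in enumerate(fit.spec.covariates, start=1):
        beta = float(fit.params.beta[j])
        se = float(fit.standard_errors[j])
        label = _VARIABLE_LABELS[cov]
        if np.isfinite(se) and se > 0:
            z = beta / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            lo, hi = beta - 1.96 * se, beta + 1.96 * se
        else:
            p, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append(AssociationRow(label, beta, lo, hi, p, "wald"))
        if boot is not None:
            name = names[j]
            lo_b, hi_b = boot.ci.get(name, (float("nan"), float("nan")))
            p_b = boot.p_values.get(name, float("nan"))
            rows.append(AssociationRow(label, beta, lo_b, hi_b, p_b, "bootstrap_percentile"))
    return rows


def format_p(p: float) -> str:
    """Rendered-table convention: probabilities below 0.001 display as '<0.001'."""
    if not np.isfinite(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class PipelineConfig:
    """Everything one comparison run needs; serialisable to/from YAML or JSON."""

    data: str | None = None  # cohort CSV path; None -> synthesise
    cohort: CohortConfig | None = None
    outcomes: tuple[str, ...] = ("vcat", "moca")
    orientations: tuple[str, ...] = ("original", "inverse")
    scenarios: tuple[str, ...] = ("intercept_only", "with_covariates")
    families: tuple[str, ...] = FAMILY_NAMES
    covariates: tuple[str, ...] = ("age", "sex", "education")
    bootstrap_B: int = 0  # 0 disables bootstrapping
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        for name in ("outcomes", "orientations", "families", "scenarios"):
            if not getattr(self, name):
                raise ConfigurationError(f"{name} must not be empty")
        bad = set(self.families) - set(FAMILY_NAMES)
        if bad:
            raise ConfigurationError(f"unknown families {sorted(bad)}")
        bad = set(self.scenarios) - {"intercept_only", "with_covariates"}
        if bad:
            raise ConfigurationError(f"unknown scenarios {sorted(bad)}")


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    gof: pd.DataFrame
    predicted: pd.DataFrame
    associations: pd.DataFrame
    bootstrap_gof: pd.DataFrame | None
    manifest: dict
    fits: dict = field(default_factory=dict)  # (outcome, orientation, scenario, family) -> FitResult


def _gof_frame(rows: list[GOFRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def run_comparison(config: PipelineConfig) -> ReportBundle:
    """Fit every requested model, assemble comparison grids and association tables."""
    config.validate()
    if config.data is not None:
        frame = read_cohort_csv(config.data)
        data_source = str(config.data)
    else:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        frame = cohort_to_frame(generate_cohort(cohort_cfg))
        data_source = f"synthetic(seed={cohort_cfg.seed}, n={cohort_cfg.n})"

    gof_rows: list[GOFRow] = []
    pred_frames: list[pd.DataFrame] = []
    fits: dict = {}
    for outcome in config.outcomes:
        for orientation in config.orientations:
            for scenario in config.scenarios:
                covs = config.covariates if scenario == "with_covariates" else ()
                for family in config.families:
                    spec = ModelSpec(family=family, outcome=outcome,
                                     orientation=orientation, covariates=covs)
                    try:
                        fit = fit_model(frame, spec)
                    except SkewfitError as exc:
                        warnings.warn(f"{family}/{outcome}/{orientation}/{scenario}: {exc}",
                                      stacklevel=2)
                        gof_rows.append(GOFRow(family, scenario, orientation, outcome,
                                               len(frame), 0, float("nan"), float("nan"),
                                               float("nan"), False))
                        continue
                    fits[(outcome, orientation, scenario, family)] = fit
                    gof_rows.append(goodness_of_fit(fit))
                    if fit.converged:
                        pred = predicted_score_distribution(fit, frame)
                        pred_frames.append(pd.DataFrame({
                            "outcome": outcome, "orientation": orientation,
                            "scenario": scenario, "family": family,
                            "score": pred.scores, "observed": pred.observed,
                            "expected": pred.expected,
                        }))

    gof = _gof_frame(gof_rows)

    # association table for the AIC-best converged covariate model per
    # outcome x orientation (plus bootstrap rows when enabled)
    assoc_rows = []
    boot_gof_rows = []
    if "with_covariates" in config.scenarios:
        for outcome in config.outcomes:
            for orientation in config.orientations:
                rows = [r for r in gof_rows
                        if (r.outcome, r.orientation, r.scenario)
                        == (outcome, orientation, "with_covariates")]
                ranked = [r for r in rank_models(rows, "aic") if r.converged]
                if not ranked:
                    continue
                best = ranked[0]
                fit = fits[(outcome, orientation, "with_covariates", best.family)]
                boot = None
                if config.bootstrap_B > 0:
                    boot = bootstrap_fit(frame, fit.spec, B=config.bootstrap_B,
                                         seed=config.seed)
                    for stat, (mean, med) in boot.gof_summary.items():
                        boot_gof_rows.append({
                            "outcome": outcome, "orientation": orientation,
                            "scenario": "with_covariates", "family": best.family,
                            "statistic": stat, "mean": mean, "median": med,
                            "n_failed": boot.n_failed, "B": boot.B,
                        })
                for row in association_table(fit, boot):
                    assoc_rows.append({
                        "outcome": outcome, "orientation": orientation,
                        "family": best.family, **dataclasses.asdict(row),
                        "p_display": format_p(row.p_value),
                    })

    predicted = (pd.concat(pred_frames, ignore_index=True)
                 if pred_frames else pd.DataFrame())
    associations = pd.DataFrame(assoc_rows)
    bootstrap_gof = pd.DataFrame(boot_gof_rows) if boot_gof_rows else None

    manifest = {
        "skewfit_version": _pkg_version,
        "data_source": data_source,
        "n": int(len(frame)),
        "seed": config.seed,
        "bootstrap_B": config.bootstrap_B,
        "outcomes": list(config.outcomes),
        "orientations": list(config.orientations),
        "scenarios": list(config.scenarios),
        "families": list(config.families),
        "positivity_shifts": {
            f"{k[0]}/{k[1]}/{k[3]}": fit.shift
            for k, fit in fits.items() if fit.shift
        },
    }

    bundle = ReportBundle(gof, predicted, associations, bootstrap_gof, manifest, fits)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        gof.to_csv(out / "gof_grid.csv", index=False)
        predicted.to_csv(out / "predicted_distributions.csv", index=False)
        associations.to_csv(out / "associations.csv", index=False)
        if bootstrap_gof is not None:
            bootstrap_gof.to_csv(out / "gof_grid_bootstrap.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle
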