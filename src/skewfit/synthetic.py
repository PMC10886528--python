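"""Synthetic cohorts with the structure of an early-neurocognitive-disorder study.

Real screening data of this kind are rarely deposited, so the package ships a
generator that emulates the marginal structure such cohorts show: ~880
participants, age around 63.5 +/- 7.8 years, roughly one third male, about 11
years of education, and two 0-30 screening totals — a unimodal left-skewed one
(MoCA-like) and a bimodal left-skewed one (VCAT-like).

Mechanism
---------
Inverse scores (error counts, 30 - score) are drawn from generalised-Poisson
regressions on age, sex and education with a log link:

* inverse MoCA: a single GP component (unimodal right-skew);
* inverse VCAT: a two-component GP mixture with well-separated means
  (weights 0.75/0.25), giving the bimodal shape seen when a cohort blends a
  mildly and a more clearly impaired subgroup.

Covariates are centred before entering the linear predictor, and the
coefficient signs on the inverse (error) scale are: age positive (older ->
more errors), female negative, education negative.  Draws above 30 are
rejected and redrawn so scores never leave [0, 30] and no artificial spike
appears at the ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError
from .families import ParameterSet, get_family

__all__ = [
    "SubjectRecord",
    "CohortConfig",
    "generate_cohort",
    "simulate_from_family",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]


@dataclass
class SubjectRecord:
    """One participant: demographics plus 0-30 integer test scores."""

    id: int
    age: float
    sex: str  # 'male' | 'female'
    education: float
    scores: dict[str, int]

    def __post_init__(self):
        if self.id <= 0:
            raise DomainError(f"subject id must be positive, got {self.id}")
        if not (np.isfinite(self.age) and self.age >= 0):
            raise DomainError(f"subject {self.id}: age must be finite and >= 0")
        if not (np.isfinite(self.education) and self.education >= 0):
            raise DomainError(f"subject {self.id}: education must be finite and >= 0")
        if self.sex not in ("male", "female"):
            raise DomainError(f"subject {self.id}: sex must be 'male' or 'female'")
        for name, s in self.scores.items():
            if not (0 <= s <= 30 and float(s).is_integer()):
                raise DomainError(
                    f"subject {self.id}: {name} score {s} outside integer range [0, 30]"
                )


@dataclass
class CohortConfig:
    """Generator settings; the defaults define the reference study conditions."""

    n: int = 883
    seed: int = 0
    age_mean: float = 63.5
    age_sd: float = 7.8
    age_range: tuple[float, float] = (40.0, 90.0)
    p_male: float = 0.342
    edu_mean: float = 11.6
    edu_sd: float = 4.0
    edu_max: float = 23.0
    # covariate effects on the log mean of the inverse (error) score;
    # covariates are centred at (age_mean, 0, edu_mean); female is 0/1
    beta_age: float = 0.02
    beta_female: float = -0.05
    beta_education: float = -0.06
    # inverse-MoCA mechanism: one GP component (unimodal)
    moca_inverse_mean: float = 4.4
    moca_delta: float = 0.45
    # inverse-VCAT mechanism: two GP components (bimodal)
    vcat_mix_weights: tuple[float, float] = (0.75, 0.25)
    vcat_component_means: tuple[float, float] = (3.5, 11.0)
    vcat_component_deltas: tuple[float, float] = (0.20, 0.15)
    max_score: int = 30

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigurationError(f"cohort size must be positive, got n={self.n}")
        if not 0 < self.p_male < 1:
            raise ConfigurationError(f"p_male must be in (0, 1), got {self.p_male}")
        for name in ("age_sd", "edu_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if abs(sum(self.vcat_mix_weights) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mixture weights must sum to 1, got {self.vcat_mix_weights}"
            )
        if any(w <= 0 for w in self.vcat_mix_weights):
            raise ConfigurationError("mixture weights must be positive")
        for d in (self.moca_delta, *self.vcat_component_deltas):
            if not 0 <= d < 1:
                raise ConfigurationError(f"GP dispersion must lie in [0, 1), got {d}")
        if any(m <= 0 for m in (self.moca_inverse_mean, *self.vcat_component_means)):
            raise ConfigurationError("inverse-score component means must be positive")


def _draw_gp_within_support(rng, gp, mu, delta, max_score):
    """GP draws with per-record mean mu, redrawing any value above max_score."""
    out = gp.sample(rng, np.log(mu), delta)
    out = np.atleast_1d(out)
    for _ in range(1000):
        over = out > max_score
        if not np.any(over):
            return out
        out[over] = np.atleast_1d(gp.sample(rng, np.log(mu[over]), delta))
    raise ConfigurationError(
        "could not keep inverse scores within support; component mean too close to 30"
    )


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw a synthetic cohort; identical config and seed give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    female = (rng.random(n) >= config.p_male).astype(float)
    shape = (config.edu_mean / config.edu_sd) ** 2
    scale = config.edu_sd**2 / config.edu_mean
    education = np.clip(np.round(rng.gamma(shape, scale, size=n)), 0, config.edu_max)

    eta_cov = (
        config.beta_age * (age - config.age_mean)
        + config.beta_female * female
        + config.beta_education * (education - config.edu_mean)
    )
    gp = get_family("gp")

    # unimodal inverse score (MoCA-like)
    mu_moca = config.moca_inverse_mean * np.exp(eta_cov)
    inv_moca = _draw_gp_within_support(rng, gp, mu_moca, config.moca_delta, config.max_score)

    # bimodal inverse score (VCAT-like): component per subject, then GP draw
    comp = (rng.random(n) >= config.vcat_mix_weights[0]).astype(int)
    inv_vcat = np.empty(n, dtype=np.int64)
    for c in (0, 1):
        rows = np.flatnonzero(comp == c)
        if rows.size == 0:
            continue
        mu_c = config.vcat_component_means[c] * np.exp(eta_cov[rows])
        inv_vcat[rows] = _draw_gp_within_support(
            rng, gp, mu_c, config.vcat_component_deltas[c], config.max_score
        )

    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                id=i + 1,
                age=float(age[i]),
                sex="female" if female[i] else "male",
                education=float(education[i]),
                scores={
                    "vcat": int(config.max_score - inv_vcat[i]),
                    "moca": int(config.max_score - inv_moca[i]),
                },
            )
        )
    return records


def simulate_from_family(family: str, params: ParameterSet, covariates=None,
                         n: int | None = None, seed: int = 0) -> np.ndarray:
    """Draw outcomes from one of the eight candidate families.

    ``covariates`` is a design matrix (intercept column included) whose row
    count fixes the number of draws; otherwise ``n`` draws use the intercept
    alone.  Count families return non-negative integers, positive-continuous
    families values > 0; the draw is deterministic under a fixed seed.
    """
    fam = get_family(family)
    if not fam.admissible_aux(params.aux if fam.n_aux else None):
        raise DomainError(
            f"{fam.name}: inadmissible auxiliary parameter {fam.aux_name}={params.aux}"
        )
    if covariates is not None:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[1] != params.beta.size:
            raise DomainError(
                f"design matrix has {X.shape[1]} columns but beta has {params.beta.size}"
            )
        eta = X @ params.beta
    else:
        if n is None or n <= 0:
            raise ConfigurationError(f"n must be a positive integer, got {n}")
        eta = np.full(n, params.beta[0])
    rng = np.random.default_rng(seed)
    return np.asarray(fam.sample(rng, eta, params.aux))


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "age", "sex", "education", "vcat", "moca"]


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame with columns id,age,sex,education,<scores>."""
    rows = []
    for r in records:
        row = {"id": r.id, "age": r.age, "sex": r.sex, "education": r.education}
        row.update(r.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectRecord]:
    score_cols = [c for c in frame.columns if c not in ("id", "age", "sex", "education")]
    return [
        SubjectRecord(
            id=int(row["id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            education=float(row["education"]),
            scores={c: int(row[c]) for c in score_cols},
        )
        for _, row in frame.iterrows()
    ]


def write_cohort_csv(records: list[SubjectRecord], path) -> None:
    cohort_to_frame(records)[_CSV_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_CSV_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"cohort file {path} lacks columns {sorted(missing)}")
    return frame
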