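"""Unrestricted-random bootstrap with percentile confidence intervals.

Resampling draws records with equal probability and with replacement at a
100% sampling rate, so every bootstrap sample has the size of the original
cohort and records may appear multiple times.  Percentile intervals follow
the tail-exclusion rule: sort the replicate estimates, drop
``floor(0.025 * B)`` values in each tail, and report the minimum and maximum
of what remains — at B = 10,000 this is the interval between the 251st and
the 9,750th order statistics.  Endpoints are therefore always elements of the
replicate draws, never interpolated.

Replicate r uses an RNG stream spawned deterministically from (seed, r), so
results do not depend on execution order.  Replicates whose fit fails to
converge are dropped (not retried — retrying would bias the resampling
distribution) and counted in ``n_failed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparison import goodness_of_fit
from .exceptions import DataError, InferenceError
from .fitting import ModelSpec, fit_model, _as_frame

__all__ = ["BootstrapResult", "resample", "percentile_ci", "bootstrap_fit"]


@dataclass
class BootstrapResult:
    """Replicate-level estimates and GOF values with percentile summaries."""

    spec: ModelSpec
    B: int
    seed: int
    param_names: list[str]
    draws: np.ndarray  # (B_successful, n_params), natural scale
    gof_draws: pd.DataFrame  # columns minus2LL, aic, bic over successful replicates
    n_failed: int
    level: float = 0.95
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    gof_summary: dict[str, tuple[float, float]] = field(default_factory=dict)  # stat -> (mean, median)
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def n_successful(self) -> int:
        return self.draws.shape[0]


def resample(records, rng: np.random.Generator):
    """One bootstrap sample: n draws with replacement from n records."""
    if isinstance(records, pd.DataFrame):
        n = len(records)
        if n == 0:
            raise DataError("cannot resample an empty cohort")
        idx = rng.integers(0, n, size=n)
        return records.iloc[idx].reset_index(drop=True)
    records = list(records)
    n = len(records)
    if n == 0:
        raise DataError("cannot resample an empty cohort")
    idx = rng.integers(0, n, size=n)
    return [records[i] for i in idx]


def percentile_ci(draws, level: float = 0.95) -> tuple[float, float]:
    """Tail-exclusion percentile interval over bootstrap draws.

    Excludes ``floor((1-level)/2 * B)`` order statistics in each tail and
    returns the minimum and maximum of the retained central block.
    """
    draws = np.asarray(draws, dtype=float)
    draws = draws[np.isfinite(draws)]
    b = draws.size
    if b < 40:
        raise InferenceError(f"need at least 40 finite draws for a percentile CI, got {b}")
    cut = math.floor((1.0 - level) / 2.0 * b)
    s = np.sort(draws)
    return float(s[cut]), float(s[b - 1 - cut])


def bootstrap_fit(
    records,
    spec: ModelSpec,
    B: int = 10_000,
    seed: int = 0,
    *,
    level: float = 0.95,
    n_restarts: int = 0,
) -> BootstrapResult:
    """Resample-and-refit ``B`` times; summarise estimates and GOF statistics.

    The base-data fit must converge first; its estimates warm-start every
    replicate fit.  Per-coefficient two-sided bootstrap p-values use the
    sign-crossing rule ``2 * min(#{draws <= 0}, #{draws >= 0}) / B_successful``,
    floored at ``1 / B_successful`` so a p-value of exactly zero is never
    reported.
    """
    if B < 100:
        warnings.warn(f"B={B} is very small for percentile inference", stacklevel=2)
    frame = _as_frame(records)
    base = fit_model(frame, spec)
    if not base.converged:
        raise DataError(
            f"base {spec.family} fit did not converge; refusing to bootstrap"
        )

    streams = np.random.SeedSequence(seed).spawn(B)
    names = base.param_names
    draws, m2, aics, bics = [], [], [], []
    n_failed = 0
    for r in range(B):
        rng = np.random.default_rng(streams[r])
        boot = resample(frame, rng)
        try:
            fit = fit_model(boot, spec, n_restarts=n_restarts, compute_se=False,
                            start=base.params)
        except (DataError, ValueError):
            n_failed += 1
            continue
        if not fit.converged or not np.isfinite(fit.minus2LL):
            n_failed += 1
            continue
        row = goodness_of_fit(fit)
        draws.append(fit.params.as_vector())
        m2.append(row.minus2LL)
        aics.append(row.aic)
        bics.append(row.bic)

    if n_failed > 0.01 * B:
        warnings.warn(
            f"{n_failed}/{B} bootstrap replicates failed to converge and were dropped",
            stacklevel=2,
        )
    draws = np.asarray(draws) if draws else np.empty((0, len(names)))
    gof = pd.DataFrame({"minus2LL": m2, "aic": aics, "bic": bics})

    result = BootstrapResult(
        spec=spec, B=B, seed=seed, param_names=names, draws=draws,
        gof_draws=gof, n_failed=n_failed, level=level,
    )
    bs = result.n_successful
    if bs >= 40:
        for j, name in enumerate(names):
            result.ci[name] = percentile_ci(draws[:, j], level)
        n_cov = 1 + len(spec.covariates)
        for j in range(n_cov):
            d = draws[:, j]
            p = 2.0 * min(np.mean(d <= 0), np.mean(d >= 0))
            result.p_values[names[j]] = float(min(max(p, 1.0 / bs), 1.0))
        for stat in ("minus2LL", "aic", "bic"):
            result.gof_summary[stat] = (float(gof[stat].mean()), float(gof[stat].median()))
    return result
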