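"""Score-orientation and positivity transforms.

Screening totals such as the MoCA and VCAT live on 0..30 with a ceiling at
30, so the raw scores are left-skewed.  The inverse score ``30 - score``
counts errors instead of successes, turning left-skew into right-skew where
the count and positive-continuous families are at home.  The transform is an
involution: applying it twice returns the original scores.

Strictly positive families (log-normal, gamma, Weibull) cannot evaluate a
zero, so a uniform +0.5 shift is applied to *all* values whenever any value
is zero; the shift is recorded on the vector and must be carried into every
statistic computed on the shifted scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DomainError
from .families import POSITIVE_FAMILIES

__all__ = ["ScoreVector", "invert_scores", "shift_for_positive_support", "DEFAULT_SHIFT"]

#: smallest half-integer separating 0 from 1 on an integer score scale
DEFAULT_SHIFT = 0.5


@dataclass(frozen=True)
class ScoreVector:
    """A vector of test scores with its orientation and any positivity shift."""

    values: np.ndarray
    orientation: str = "original"  # 'original' | 'inverse'
    max_score: int = 30
    shift: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.orientation not in ("original", "inverse"):
            raise DomainError(f"unknown orientation {self.orientation!r}")
        if self.shift < 0:
            raise DomainError(f"shift must be non-negative, got {self.shift}")

    @property
    def n(self) -> int:
        return self.values.size


def invert_scores(scores: ScoreVector) -> ScoreVector:
    """Map each score s to ``max_score - s`` and toggle the orientation flag.

    Only unshifted vectors may be inverted; every value must lie in
    [0, max_score] or a :class:`DomainError` names the offending record.
    """
    if scores.shift != 0:
        raise DomainError("cannot invert a shifted score vector; invert before shifting")
    v = scores.values
    bad = np.flatnonzero((v < 0) | (v > scores.max_score) | ~np.isfinite(v))
    if bad.size:
        raise DomainError(
            f"score out of range [0, {scores.max_score}] at record index {bad[0]} "
            f"(value {v[bad[0]]}); {bad.size} offending record(s) in total"
        )
    flipped = "inverse" if scores.orientation == "original" else "original"
    return ScoreVector(scores.max_score - v, orientation=flipped, max_score=scores.max_score)


def shift_for_positive_support(
    scores: ScoreVector, family: str, shift: float = DEFAULT_SHIFT
) -> ScoreVector:
    """Shift all values by ``shift`` when a positive-support family meets a zero.

    The shift is all-or-nothing: either every value moves or none does, so the
    ordering of records is preserved.  Families with full or count support are
    returned unchanged.
    """
    if family not in POSITIVE_FAMILIES:
        return scores
    if np.all(scores.values > 0):
        return scores
    return replace(scores, values=scores.values + shift, shift=scores.shift + shift)
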