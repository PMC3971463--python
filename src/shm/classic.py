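"""Classic scale homogenization transforms and the frequency approach.

These are the established methods a harmonization study starts from:

* **Rank numbers** — option ``i`` scores ``i`` (1-based), semantics ignored.
* **Linear stretch** — options mapped to equally spaced points with the
  extremes pinned to the ends of the target range (default 0–10); the
  percentage-of-scale-maximum (%SM) transform is the same idea expressed
  on a 0–100 range.
* **Fixed word values** — each verbal label carries a context-free expert
  rating reused across every scale containing it.
* **Mid-interval values** — when judges have placed option *boundaries* on
  the 0–10 continuum, each option is represented by its interval midpoint.

All of them summarize a frequency table the same way ("frequency
approach"): the transformed mean is the frequency-weighted sum of the
per-option values, and the sd follows from the same discrete distribution.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .scales import (
    BoundarySet,
    FrequencyTable,
    Lexicon,
    ResponseScale,
    ValidationError,
)

__all__ = [
    "rank_values",
    "linear_stretch_values",
    "percent_scale_maximum",
    "fixed_word_values",
    "mid_interval_values",
    "frequency_mean",
    "frequency_sd",
]


def rank_values(scale: ResponseScale) -> np.ndarray:
    """Consecutive rank numbers 1..k aligned with ascending option order."""
    return np.arange(1, scale.n_options + 1, dtype=float)


def linear_stretch_values(scale: ResponseScale, lo: float = 0.0, hi: float = 10.0) -> np.ndarray:
    """k equally spaced values from ``lo`` to ``hi`` inclusive.

    For a 5-option scale the default range gives [0, 2.5, 5, 7.5, 10].
    """
    if not lo < hi:
        raise ValidationError(f"need lo < hi, got lo={lo}, hi={hi}")
    return np.linspace(lo, hi, scale.n_options)


def percent_scale_maximum(mean_score: float, n: int) -> float:
    """%SM = (mean score / n) x 100 for scores anchored 0..n."""
    if n < 1:
        raise ValidationError(f"scale maximum n must be >= 1, got {n}")
    if not 0 <= mean_score <= n:
        raise ValidationError(f"mean score {mean_score} outside [0, {n}]")
    return mean_score / n * 100.0


def fixed_word_values(scale: ResponseScale, lexicon: Lexicon) -> np.ndarray:
    """Look up each option label's fixed word value.

    The method deliberately ignores scale context, so the result need not be
    monotone in option order.  Raises listing *all* labels absent from the
    lexicon, not just the first.
    """
    missing = [str(o) for o in scale.options if o not in lexicon]
    if missing:
        raise ValidationError(f"labels missing from lexicon: {missing}")
    return np.array([lexicon[o] for o in scale.options], dtype=float)


def mid_interval_values(bounds: BoundarySet) -> np.ndarray:
    """Midpoint of each option's interval on the continuum."""
    lo = np.asarray(bounds.lower_bounds)
    hi = bounds.uppers()
    return (lo + hi) / 2.0


def _aligned(values: Sequence[float], freqs: FrequencyTable) -> tuple:
    v = np.asarray(values, dtype=float)
    p = freqs.rel()
    if v.shape != p.shape:
        raise ValidationError(f"{v.size} values for {p.size} frequencies")
    return v, p


def frequency_mean(values: Sequence[float], freqs: FrequencyTable) -> float:
    """Frequency-approach mean: the weighted sum of per-option values."""
    v, p = _aligned(values, freqs)
    return float(v @ p)


def frequency_sd(values: Sequence[float], freqs: FrequencyTable, *, n: int = None) -> float:
    """Frequency-approach standard deviation over the discrete distribution.

    Population form by default (divide by 1 over relative frequencies); pass
    the total respondent count ``n`` to apply the n/(n-1) sample correction
    when the weights were counts.
    """
    v, p = _aligned(values, freqs)
    m = v @ p
    var = float(p @ (v - m) ** 2)
    if n is not None:
        if n < 2:
            raise ValidationError(f"sample correction needs n >= 2, got {n}")
        var *= n / (n - 1)
    return math.sqrt(var)
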