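"""Scenario generator: latent beta scores observed through boundary sets.

The generator emulates the kind of data the homogenization pipeline is
built for: a population whose latent satisfaction follows a (possibly
drifting) beta distribution on [0, 10], observed each year by one or more
surveys whose response scales slice the continuum through different
boundary sets.  A wave is a multinomial draw of n respondents over the
interval probabilities, reported — as real statistical agencies do — only
as a frequency table.  An optional mode shift swaps a survey's boundary set
from a given year onward, emulating a questionnaire redesign that changes
how respondents use the categories while the latent truth is untouched.

All randomness flows from explicit seeds; the same scenario always yields
the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .scales import (
    BetaParams,
    BoundarySet,
    FrequencyTable,
    ValidationError,
)
from .continuum import beta_cdf, beta_mean_sd

__all__ = ["Scenario", "expected_frequencies", "simulate_wave", "simulate_panel"]


def expected_frequencies(params: BetaParams, bounds: BoundarySet) -> np.ndarray:
    """Interval probabilities p_i = F(b_i) - F(b_{i-1}); sums to 1."""
    edges = np.concatenate([[0.0], bounds.uppers()])
    return np.diff(beta_cdf(edges, params))


def simulate_wave(
    params: BetaParams,
    bounds: BoundarySet,
    n: int,
    seed: int,
    *,
    year: int = 0,
    survey_id: str = "sim",
    return_scores: bool = False,
):
    """Draw one survey wave of n respondents as a frequency table.

    Category counts are drawn directly from the multinomial over the
    interval probabilities.  With ``return_scores=True`` the per-respondent
    latent scores are also returned (sorted into categories they imply),
    for callers who need microdata-like output.
    """
    if n < 1:
        raise ValidationError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    probs = expected_frequencies(params, bounds)
    if return_scores:
        scores = 10.0 * rng.beta(params.alpha, params.beta, size=n)
        counts = np.histogram(scores, bins=np.concatenate([[0.0], bounds.uppers()]))[0]
        table = FrequencyTable(scale=bounds.scale, weights=tuple(counts.astype(float)),
                               year=year, survey_id=survey_id)
        return table, scores
    counts = rng.multinomial(n, probs / probs.sum())
    return FrequencyTable(scale=bounds.scale, weights=tuple(counts.astype(float)),
                          year=year, survey_id=survey_id)


@dataclass(frozen=True)
class Scenario:
    """A multi-year, multi-survey measurement design with one latent truth.

    ``true_params`` maps each year to the population's latent beta that
    year; ``surveys`` maps a survey id to its boundary set; ``mode_shift``
    optionally replaces one survey's boundary set from a shift year onward
    (survey_id, shift_year, new BoundarySet).  ``n`` respondents per wave.
    """

    years: tuple
    true_params: Mapping[int, BetaParams]
    surveys: Mapping[str, BoundarySet]
    n: int
    seed: int
    mode_shift: Optional[tuple] = None  # (survey_id, shift_year, BoundarySet)

    def __post_init__(self):
        years = tuple(self.years)
        object.__setattr__(self, "years", years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValidationError("years must be strictly increasing")
        if self.n < 1:
            raise ValidationError(f"sample size must be >= 1, got {self.n}")
        missing = [y for y in years if y not in self.true_params]
        if missing:
            raise ValidationError(f"no true parameters for years {missing}")
        if self.mode_shift is not None:
            sid, shift_year, new_bounds = self.mode_shift
            if sid not in self.surveys:
                raise ValidationError(f"mode shift names unknown survey {sid!r}")
            if not isinstance(new_bounds, BoundarySet):
                raise ValidationError("mode shift replacement must be a BoundarySet")

    def bounds_for(self, survey_id: str, year: int) -> BoundarySet:
        if self.mode_shift is not None:
            sid, shift_year, new_bounds = self.mode_shift
            if survey_id == sid and year >= shift_year:
                return new_bounds
        return self.surveys[survey_id]


def simulate_panel(scenario: Scenario):
    """Simulate every (survey, year) wave plus a truth record.

    Returns ``(tables, truth)``: ``tables[survey_id]`` is the list of yearly
    frequency tables; ``truth`` is a DataFrame with the per-year true mean
    and sd implied by the latent beta.  Wave seeds are derived from the
    scenario seed so each wave is independent yet reproducible.
    """
    root = np.random.default_rng(scenario.seed)
    tables = {}
    for s_idx, survey_id in enumerate(sorted(scenario.surveys)):
        tables[survey_id] = []
        for y_idx, year in enumerate(scenario.years):
            wave_seed = int(root.integers(0, 2**31 - 1))
            table = simulate_wave(
                scenario.true_params[year],
                scenario.bounds_for(survey_id, year),
                scenario.n,
                wave_seed,
                year=year,
                survey_id=survey_id,
            )
            tables[survey_id].append(table)
    truth_rows = []
    for year in scenario.years:
        mean, sd = beta_mean_sd(scenario.true_params[year])
        truth_rows.append({"year": year, "true_mean": mean, "true_sd": sd})
    return tables, pd.DataFrame(truth_rows)
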