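"""The reference distribution method.

Judge-assessed boundaries reflect what option labels *mean*; they do not
guarantee that different surveys about the same population line up.  The
reference distribution method instead anchors every scale to one
deliberately chosen item in a reference year: the beta distribution fitted
to that item becomes the *reference distribution*, and the boundary between
options i and i+1 of any other scale fielded the same year is placed where
the reference CDF equals the cumulative relative frequency through option i
(quantile matching).  Those boundaries are then held fixed for the whole
time series of that survey; each year is transformed by refitting a beta
under the fixed boundaries.

When a survey changes design or mode, the old boundaries stop being valid.
Re-anchoring derives a fresh boundary set for the other side of the change:
the beta fitted in the bridge year (ideally a double measurement fielded in
both designs, else the adjacent year) becomes a new reference, and quantile
matching against the other-design table yields its boundaries.

Known degeneracy (by construction, not a bug): a survey fielded only once
and transformed against a reference returns the reference distribution
itself — quantile matching followed by refitting on the same table is the
identity.  The method needs at least two waves to add information.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scales import (
    BetaParams,
    BoundarySet,
    BoundarySource,
    FrequencyTable,
    HomogenizedSeries,
    ValidationError,
    YearRecord,
)
from .continuum import FitError, beta_mean_sd, beta_quantile, fit_beta

__all__ = [
    "derive_boundaries",
    "reconstruct_reference",
    "transform_series",
    "reanchor",
    "combine_surveys",
]

# Cumulative frequencies are clipped away from {0, 1} before inversion: the
# quantile function has infinite slope at the endpoints for many shapes.
_P_CLIP = 1e-9


def derive_boundaries(ref: BetaParams, freqs: FrequencyTable) -> BoundarySet:
    """Quantile-match a frequency table against a reference distribution.

    Upper boundary of option i (i < k) is the reference quantile at the
    cumulative relative frequency through option i; the last boundary is 10
    by definition.  Needs at least 3 options — with 2 the subsequent refit
    is undetermined, so the method is invalid.
    """
    k = freqs.scale.n_options
    if k < 3:
        raise ValidationError(
            "reference distribution method is invalid for fewer than three options"
        )
    P = freqs.cumulative()[:-1]
    if P[0] <= 0.0:
        warnings.warn(
            "first option has zero frequency: its derived interval has zero length",
            stacklevel=2,
        )
    uppers = beta_quantile(np.clip(P, _P_CLIP, 1.0 - _P_CLIP), ref)
    return BoundarySet(
        scale=freqs.scale,
        upper_bounds=tuple(np.append(uppers, 10.0)),
        source=BoundarySource.reference_derived,
    )


def reconstruct_reference(
    bounds: BoundarySet, freqs: FrequencyTable, criterion="cdf_lsq"
) -> BetaParams:
    """Recover a reference beta from a published boundary column + frequencies.

    Fits the beta CDF through the (interior boundary, cumulative frequency)
    pairs, least squares on CDF values by default.  Useful when the raw data
    behind a published reference are unavailable but its derived boundaries
    for some scale are in print.
    """
    return fit_beta(bounds, freqs, criterion=criterion).params


def transform_series(
    bounds: BoundarySet, yearly: Iterable[FrequencyTable], criterion="chi2"
) -> HomogenizedSeries:
    """Fit a beta per year under fixed boundaries.

    Per-year fit failures are recorded on the year's record and do not abort
    the remaining years.
    """
    yearly = list(yearly)
    years = [t.year for t in yearly]
    if len(set(years)) != len(years):
        raise ValidationError(f"duplicate years in series: {sorted(years)}")
    survey_ids = {t.survey_id for t in yearly}
    if len(survey_ids) > 1:
        raise ValidationError(f"mixed survey ids in one series: {sorted(survey_ids)}")
    records = []
    for table in yearly:
        if table.scale.n_options != bounds.scale.n_options:
            records.append(YearRecord(table.year, None, None, None,
                                      error="scale does not match boundary set"))
            continue
        try:
            fit = fit_beta(bounds, table, criterion=criterion)
            mean, sd = beta_mean_sd(fit.params)
            records.append(YearRecord(table.year, fit.params, mean, sd))
        except (FitError, ValidationError) as exc:
            records.append(YearRecord(table.year, None, None, None, error=str(exc)))
    return HomogenizedSeries(
        survey_id=yearly[0].survey_id if yearly else bounds.scale.item_code,
        boundaries=bounds,
        records=tuple(records),
    )


def reanchor(
    bounds: BoundarySet,
    bridge: FrequencyTable,
    target: FrequencyTable,
    criterion="chi2",
) -> BoundarySet:
    """Derive boundaries for the other side of a survey design change.

    ``bounds`` are the boundaries valid for the regime in which ``bridge``
    was measured.  ``bridge`` should be the double measurement fielded in
    the changed design during the change year when one exists, otherwise
    the table of the year adjacent to the change (usable when year-to-year
    movement is small).  The beta fitted to (bounds, bridge) becomes the new
    reference; quantile matching it against ``target`` — the same-period
    table under the other design — yields that design's boundary set.
    """
    if bridge is None:
        raise ValidationError("re-anchoring needs a bridge table (double measurement or adjacent year)")
    new_ref = fit_beta(bounds, bridge, criterion=criterion).params
    return derive_boundaries(new_ref, target)


def combine_surveys(
    series_a: HomogenizedSeries,
    series_b: HomogenizedSeries,
    reference_year: int,
) -> pd.DataFrame:
    """Merge two homogenized series into one year-by-year mean table.

    Both series must cover the reference year (the year their boundary
    chains were tied together).  Overlapping years report both means and
    their average, flagged; years covered by one survey carry that survey's
    mean.  Columns: year, mean_a, mean_b, mean, overlap.
    """
    ma, mb = series_a.means(), series_b.means()
    if reference_year not in ma or reference_year not in mb:
        raise ValidationError(
            f"reference year {reference_year} must appear (successfully fitted) in both series"
        )
    rows = []
    for year in sorted(set(ma) | set(mb)):
        a, b = ma.get(year), mb.get(year)
        overlap = a is not None and b is not None
        mean = (a + b) / 2.0 if overlap else (a if a is not None else b)
        rows.append({"year": year, "mean_a": a, "mean_b": b, "mean": mean, "overlap": overlap})
    return pd.DataFrame(rows)
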