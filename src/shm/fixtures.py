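"""Bundled example tables: two Dutch life-satisfaction items, year 2008.

The package ships the published summary tables for the POLS item
(O-SLL-c-sq-v-5-d, five verbal options, asymmetric) and the Eurobarometer
item (O-SLL-u-sq-v-4-b, four verbal options), as used throughout the
documentation and tests: their 2008 frequency distributions, the
judge-assessed boundary sets, the boundary columns derived from the
ESS-2008 reference distribution, the re-anchored POLS columns for the 1997
and 1994 design changes, and the three published fixed word values.

Sources list options most-positive-first; everything here is already in the
package's ascending internal order.
"""

from __future__ import annotations

from .scales import (
    BoundarySet,
    BoundarySource,
    FrequencyTable,
    Lexicon,
    ResponseScale,
    ScaleKind,
)

__all__ = ["POLS_SCALE", "EB_SCALE", "load_fixture", "fixture_names"]

POLS_SCALE = ResponseScale(
    item_code="O-SLL-c-sq-v-5-d",
    kind=ScaleKind.verbal,
    options=(
        "Not very satisfied",
        "Fairly satisfied",
        "Satisfied",
        "Very satisfied",
        "Extraordinarily satisfied",
    ),
)

EB_SCALE = ResponseScale(
    item_code="O-SLL-u-sq-v-4-b",
    kind=ScaleKind.verbal,
    options=(
        "Not at all satisfied",
        "Not very satisfied",
        "Fairly satisfied",
        "Very satisfied",
    ),
)


def _freq(scale, weights, survey_id):
    return FrequencyTable(scale=scale, weights=weights, year=2008, survey_id=survey_id)


def _bounds(scale, uppers, source):
    return BoundarySet(scale=scale, upper_bounds=uppers, source=source)


_REGISTRY = {
    # Frequencies 2008 (%), ascending
    "pols2008": lambda: _freq(POLS_SCALE, (3.4, 7.6, 45.1, 35.5, 8.4), "POLS"),
    "eb2008": lambda: _freq(EB_SCALE, (0.6, 3.1, 44.8, 51.5), "Eurobarometer"),
    # Judge-assessed upper boundaries
    "pols_judges": lambda: _bounds(
        POLS_SCALE, (3.6, 5.3, 7.2, 8.8, 10.0), BoundarySource.judges
    ),
    "eb_judges": lambda: _bounds(EB_SCALE, (3.0, 5.3, 7.9, 10.0), BoundarySource.judges),
    # Boundaries derived from the ESS-2008 reference distribution
    "pols_ref_ess2008": lambda: _bounds(
        POLS_SCALE, (4.8, 5.7, 7.8, 9.0, 10.0), BoundarySource.reference_derived
    ),
    "eb_ref_ess2008": lambda: _bounds(
        EB_SCALE, (3.6, 4.7, 7.5, 10.0), BoundarySource.reference_derived
    ),
    # Re-anchored POLS boundaries at the 1997 and 1994 design changes
    "pols_ref_1997": lambda: _bounds(
        POLS_SCALE, (4.9, 5.8, 7.5, 8.8, 10.0), BoundarySource.reference_derived
    ),
    "pols_ref_1994": lambda: _bounds(
        POLS_SCALE, (4.5, 5.5, 7.2, 8.6, 10.0), BoundarySource.reference_derived
    ),
    # Published fixed word values (expert panel, 0-10)
    "lexicon_paper": lambda: Lexicon(
        entries={"fairly satisfied": 6.5, "very happy": 9.3, "not very happy": 3.7}
    ),
}


def fixture_names() -> list:
    return sorted(_REGISTRY)


def load_fixture(name: str):
    """Return the named bundled table as a validated domain object."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}") from None
    return factory()
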