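"""Data model for survey rating scales and their summaries.

A survey item offers an ordered set of response options (verbal labels or
numeric anchors).  Published results usually arrive as a *frequency table* —
the share of respondents choosing each option in one survey year.  Scale
homogenization maps those options onto a common 0–10 continuum, either as
point values or as sub-intervals delimited by a *boundary set*.

Everything downstream (the classic transforms, the beta-distribution
continuum fit, the reference-distribution method) consumes the types defined
here.  Internal convention: options are always stored in ascending order of
the measured construct, least positive first.  Published tables frequently
list the most positive option first; readers must be told the input order
and reverse as needed.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "ScaleKind",
    "BoundarySource",
    "ValidationError",
    "ResponseScale",
    "FrequencyTable",
    "BoundarySet",
    "BetaParams",
    "Lexicon",
    "YearRecord",
    "HomogenizedSeries",
    "normalize_frequencies",
    "validate_boundary_set",
    "round_display",
    "read_frequency_csv",
    "write_frequency_csv",
    "read_scale_json",
    "write_scale_json",
    "read_boundary_json",
    "write_boundary_json",
    "read_lexicon_csv",
]

CONTINUUM_LO = 0.0
CONTINUUM_HI = 10.0


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class ScaleKind(str, enum.Enum):
    verbal = "verbal"
    numeric = "numeric"


class BoundarySource(str, enum.Enum):
    judges = "judges"
    reference_derived = "reference_derived"
    numeric_equal_width = "numeric_equal_width"


def round_display(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, for display only.

    Matches the convention of printed survey tables (4.45 -> 4.5); Python's
    built-in banker's rounding would give 4.4.  All computation stays at
    full precision — use this only when formatting results.
    """
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def normalize_frequencies(weights: Sequence[float]) -> np.ndarray:
    """Normalize nonnegative weights (percents or counts) to relative frequencies.

    Idempotent: an already-normalized vector is returned unchanged up to
    floating-point error.  Raises :class:`ValidationError` naming the first
    offending index for negative entries, and for an all-zero vector.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValidationError("need at least 2 weights in a 1-d sequence")
    neg = np.flatnonzero(w < 0)
    if neg.size:
        raise ValidationError(f"negative weight at index {neg[0]}: {w[neg[0]]}")
    total = w.sum()
    if total <= 0:
        raise ValidationError("weights sum to zero; at least one must be positive")
    return w / total


@dataclass(frozen=True)
class ResponseScale:
    """An ordered response scale for one survey item.

    ``options`` are stored least-positive first.  For verbal scales they are
    unique labels; for numeric scales, strictly increasing anchor values.
    ``item_code`` is an opaque identifier (e.g. a WDH-style code such as
    ``O-SLL-c-sq-v-5-d``) carried through to reports.
    """

    item_code: str
    kind: ScaleKind
    options: tuple

    def __post_init__(self):
        object.__setattr__(self, "kind", ScaleKind(self.kind))
        object.__setattr__(self, "options", tuple(self.options))
        if len(self.options) < 2:
            raise ValidationError("a response scale needs at least 2 options")
        if self.kind is ScaleKind.verbal:
            if len(set(self.options)) != len(self.options):
                raise ValidationError("duplicate option labels in verbal scale")
        else:
            vals = [float(v) for v in self.options]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValidationError("numeric anchors must be strictly increasing")

    @property
    def n_options(self) -> int:
        return len(self.options)


@dataclass(frozen=True)
class FrequencyTable:
    """Relative frequencies over a scale's options for one survey/year.

    ``weights`` are kept as read (percents or counts); ``rel_freqs`` is the
    normalized vector, aligned index-for-index with ``scale.options``.
    """

    scale: ResponseScale
    weights: tuple
    year: int
    survey_id: str
    rel_freqs: tuple = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.weights) != self.scale.n_options:
            raise ValidationError(
                f"{len(self.weights)} weights for {self.scale.n_options} options"
            )
        rel = normalize_frequencies(self.weights)
        assert abs(rel.sum() - 1.0) < 1e-9
        object.__setattr__(self, "rel_freqs", tuple(rel))

    def rel(self) -> np.ndarray:
        return np.asarray(self.rel_freqs)

    def cumulative(self) -> np.ndarray:
        """Cumulative relative frequencies; last element is 1 by construction."""
        return np.cumsum(self.rel())

    def reversed(self) -> "FrequencyTable":
        """Mirror the table (used when the source lists options descending)."""
        return FrequencyTable(
            scale=ResponseScale(self.scale.item_code, self.scale.kind, self.scale.options[::-1]),
            weights=self.weights[::-1],
            year=self.year,
            survey_id=self.survey_id,
        )


@dataclass(frozen=True)
class BoundarySet:
    """Upper boundaries on [0, 10] assigning each option a sub-interval.

    Option ``i`` occupies ``(upper_bounds[i-1], upper_bounds[i]]`` with an
    implicit lower bound of 0 for the first option; the last upper bound is
    exactly 10.  Non-decreasing sequences are allowed: a repeated value gives
    a zero-length interval (an option nobody can fall into).
    """

    scale: ResponseScale
    upper_bounds: tuple
    source: BoundarySource

    def __post_init__(self):
        object.__setattr__(self, "source", BoundarySource(self.source))
        ub = tuple(float(b) for b in self.upper_bounds)
        object.__setattr__(self, "upper_bounds", ub)
        if len(ub) != self.scale.n_options:
            raise ValidationError(
                f"{len(ub)} boundaries for {self.scale.n_options} options"
            )
        if any(b < CONTINUUM_LO or b > CONTINUUM_HI for b in ub):
            raise ValidationError(f"boundaries must lie in [0, 10], got {ub}")
        if any(b < a for a, b in zip(ub, ub[1:])):
            raise ValidationError(f"boundaries must be non-decreasing, got {ub}")
        if ub[-1] != CONTINUUM_HI:
            raise ValidationError(f"last boundary must be 10, got {ub[-1]}")

    @property
    def lower_bounds(self) -> tuple:
        return (CONTINUUM_LO,) + self.upper_bounds[:-1]

    def intervals(self) -> list:
        return list(zip(self.lower_bounds, self.upper_bounds))

    def uppers(self) -> np.ndarray:
        return np.asarray(self.upper_bounds)


def validate_boundary_set(bounds: BoundarySet) -> BoundarySet:
    """Return ``bounds`` unchanged if structurally valid.

    Construction already enforces the invariants; this re-checks an instance
    that may have been built through other means (e.g. deserialized).
    """
    return BoundarySet(bounds.scale, bounds.upper_bounds, bounds.source)


@dataclass(frozen=True)
class BetaParams:
    """Shape pair of a beta distribution rescaled to support [0, 10]."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValidationError(f"alpha must be a positive finite real, got {self.alpha}")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValidationError(f"beta must be a positive finite real, got {self.beta}")


@dataclass(frozen=True)
class Lexicon:
    """Fixed word values: a context-free 0–10 rating for each option label."""

    entries: dict

    def __post_init__(self):
        bad = {k: v for k, v in self.entries.items() if not (0 <= v <= 10)}
        if bad:
            raise ValidationError(f"lexicon values outside [0, 10]: {bad}")
        object.__setattr__(self, "entries", dict(self.entries))

    def __getitem__(self, label: str) -> float:
        return self.entries[label]

    def __contains__(self, label: str) -> bool:
        return label in self.entries


@dataclass(frozen=True)
class YearRecord:
    """One transformed survey wave: fitted shapes and implied moments."""

    year: int
    params: Union[BetaParams, None]
    mean: Union[float, None]
    sd: Union[float, None]
    error: Union[str, None] = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass(frozen=True)
class HomogenizedSeries:
    """Per-year beta fits for one survey under a fixed boundary set."""

    survey_id: str
    boundaries: BoundarySet
    records: tuple

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        years = [r.year for r in self.records]
        if len(set(years)) != len(years):
            raise ValidationError("duplicate years in homogenized series")
        for r in self.records:
            if r.ok:
                implied = 10.0 * r.params.alpha / (r.params.alpha + r.params.beta)
                if abs(implied - r.mean) > 1e-9:
                    raise ValidationError(
                        f"year {r.year}: mean {r.mean} does not match params {r.params}"
                    )

    @property
    def years(self) -> list:
        return [r.year for r in self.records]

    def means(self) -> dict:
        return {r.year: r.mean for r in self.records if r.ok}

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# External formats.  Frequency CSV: `option,weight` with a required header;
# the caller declares the listing order, the weight convention, and the
# year/survey metadata (sidecar-style arguments mirroring the CLI flags).
# ---------------------------------------------------------------------------

def _ascending(options, weights, order: str):
    if order == "asc":
        return list(options), list(weights)
    if order == "desc":
        return list(options)[::-1], list(weights)[::-1]
    raise ValidationError(f"order must be 'asc' or 'desc', got {order!r}")


def read_frequency_csv(
    path,
    *,
    order: str,
    year: int,
    survey_id: str,
    weights: str = "percent",
    scale: ResponseScale = None,
) -> FrequencyTable:
    """Read an `option,weight` CSV into a validated :class:`FrequencyTable`.

    ``order`` declares how the file lists options ("asc" = least positive
    first); internally everything is ascending.  With ``weights="percent"``
    the column must sum to within [99, 101] (published tables are rounded);
    anything outside that band is treated as a transcription error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["option", "weight"]:
            raise ValidationError(f"{path}: expected header 'option,weight', got {header}")
        rows = [(r[0], float(r[1])) for r in reader if r]
    labels = [r[0] for r in rows]
    w = [r[1] for r in rows]
    labels, w = _ascending(labels, w, order)
    if weights == "percent":
        total = sum(w)
        if not (99.0 <= total <= 101.0):
            raise ValidationError(
                f"{path}: percent weights sum to {total:g}, outside [99, 101]"
            )
    elif weights != "count":
        raise ValidationError(f"weights must be 'percent' or 'count', got {weights!r}")
    if scale is None:
        scale = ResponseScale(item_code=survey_id, kind=ScaleKind.verbal, options=tuple(labels))
    else:
        if tuple(labels) != tuple(str(o) for o in scale.options) and tuple(labels) != tuple(
            scale.options
        ):
            raise ValidationError(f"{path}: option labels do not match scale {scale.item_code}")
    return FrequencyTable(scale=scale, weights=tuple(w), year=year, survey_id=survey_id)


def write_frequency_csv(table: FrequencyTable, path) -> None:
    """Write ascending `option,weight` rows; round-trips rel_freqs bit-exactly."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["option", "weight"])
        for opt, w in zip(table.scale.options, table.weights):
            writer.writerow([opt, repr(w)])


def read_scale_json(path) -> ResponseScale:
    data = json.loads(Path(path).read_text())
    options, _ = _ascending(data["options"], data["options"], data.get("order", "asc"))
    kind = ScaleKind(data["kind"])
    if kind is ScaleKind.numeric:
        options = [float(o) for o in options]
    return ResponseScale(item_code=data["item_code"], kind=kind, options=tuple(options))


def write_scale_json(scale: ResponseScale, path) -> None:
    Path(path).write_text(
        json.dumps(
            {"item_code": scale.item_code, "kind": scale.kind.value,
             "options": list(scale.options), "order": "asc"},
            indent=2,
        )
    )


def read_boundary_json(path, scale: ResponseScale) -> BoundarySet:
    data = json.loads(Path(path).read_text())
    if len(data["upper_bounds"]) != scale.n_options:
        raise ValidationError(
            f"{len(data['upper_bounds'])} boundaries for {scale.n_options}-option "
            f"scale {scale.item_code!r}"
        )
    return BoundarySet(
        scale=scale,
        upper_bounds=tuple(float(b) for b in data["upper_bounds"]),
        source=BoundarySource(data.get("source", "judges")),
    )


def write_boundary_json(bounds: BoundarySet, path) -> None:
    Path(path).write_text(
        json.dumps(
            {"item_code": bounds.scale.item_code, "source": bounds.source.value,
             "upper_bounds": list(bounds.upper_bounds)},
            indent=2,
        )
    )


def read_lexicon_csv(path) -> Lexicon:
    """Read a `label,value` CSV of fixed word values."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["label", "value"]:
            raise ValidationError(f"{path}: expected header 'label,value', got {header}")
        entries = {r[0]: float(r[1]) for r in reader if r}
    return Lexicon(entries=entries)
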