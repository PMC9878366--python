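"""Conversion of self-reports and validation measurements into absolute areas.

Three self-report dialects express tattoo extent in different units:

* ``hand_surface`` — counts of the respondent's own hand area (cm² from
  measured length × width, or a mask-sized fallback);
* ``credit_card`` — counts of a standard 30 cm² credit card;
* ``body_schemes`` — per-body-part scenario categories (10/25/50/75/100 % of
  the part tattooed) plus 5-point Likert proportions per color.

Validation measurements describe each physically measured tattoo by its
optically closest geometric shape(s), a coverage category (fraction of the
tattoo outline actually inked) and per-color area shares. Both routes end in
the same :class:`ExposureEstimate` so they can be compared head to head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .anthropometry import UnknownBodyPartError
from .colors import ColorScheme, DEFAULT_COLOR_SCHEME

#: Standard credit card area in cm².
CREDIT_CARD_AREA_CM2: float = 30.0

#: Scenario / coverage Likert categories (percent) -> fraction.
SCENARIO_FRACTIONS: dict[int, float] = {10: 0.1, 25: 0.25, 50: 0.5, 75: 0.75, 100: 1.0}

COVERAGE_CATEGORIES: tuple[int, ...] = (10, 25, 50, 75, 100)

DIALECTS: tuple[str, ...] = ("hand_surface", "credit_card", "body_schemes")

#: shape kind -> number of dimensions it requires.
SHAPE_DIMS: dict[str, int] = {"square": 1, "rectangle": 2, "circle": 1, "oval": 2}


class ShapeError(ValueError):
    """Malformed geometric shape component."""


class CoverageError(ValueError):
    """Invalid coverage category or degenerate coverage denominator."""


def shape_area(components: Sequence[tuple[str, Sequence[float]]]) -> float:
    """Area in cm² of a tattoo described by additive geometric components.

    Supported kinds: ``square`` (side²), ``rectangle`` (l×w), ``circle``
    (πr²), ``oval`` (πr₁r₂). Combinations are summed.
    """
    total = 0.0
    for kind, dims in components:
        if kind not in SHAPE_DIMS:
            raise ShapeError(f"unknown shape kind {kind!r}; known: {sorted(SHAPE_DIMS)}")
        dims = tuple(float(d) for d in dims)
        if len(dims) != SHAPE_DIMS[kind]:
            raise ShapeError(f"{kind} needs {SHAPE_DIMS[kind]} dimension(s), got {len(dims)}")
        if any(d < 0 for d in dims):
            raise ShapeError(f"negative dimension in {kind}: {dims}")
        if kind == "square":
            total += dims[0] ** 2
        elif kind == "rectangle":
            total += dims[0] * dims[1]
        elif kind == "circle":
            total += math.pi * dims[0] ** 2
        else:  # oval
            total += math.pi * dims[0] * dims[1]
    return total


def coverage_fraction_of(category: int) -> float:
    try:
        return SCENARIO_FRACTIONS[int(category)]
    except (KeyError, ValueError):
        raise CoverageError(
            f"coverage category must be one of {COVERAGE_CATEGORIES}, got {category!r}"
        ) from None


@dataclass(frozen=True)
class SelfReport:
    """One respondent's answers in a single measurement-unit dialect.

    ``entries`` holds (body_part, color, magnitude) triples. For the unit
    dialects the magnitude is a non-negative (possibly fractional) unit
    count; for ``body_schemes`` it is the per-color Likert proportion in
    {0.1, 0.25, 0.5, 0.75, 1.0} and the tattooed fraction of each part lives
    in ``scenario_entries`` as (body_part, percent category).
    ``coverage_entries`` holds (body_part, coverage category in
    {10,25,50,75,100}).
    """

    participant_id: str
    dialect: str
    entries: tuple[tuple[str, str, float], ...] = ()
    coverage_entries: tuple[tuple[str, int], ...] = ()
    scenario_entries: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"dialect must be one of {DIALECTS}, got {self.dialect!r}")
        for part, color, mag in self.entries:
            if mag < 0:
                raise ValueError(f"negative magnitude for ({part}, {color}): {mag}")
        for part, cat in self.coverage_entries:
            coverage_fraction_of(cat)
        for part, cat in self.scenario_entries:
            coverage_fraction_of(cat)  # same 5-category vocabulary
        if self.dialect != "body_schemes" and self.scenario_entries:
            raise ValueError("scenario_entries are only meaningful for body_schemes")


@dataclass(frozen=True)
class TattooRecord:
    """One physically validated tattoo."""

    participant_id: str
    tattoo_id: str
    body_part: str
    shape_components: tuple[tuple[str, tuple[float, ...]], ...]
    coverage_category: int
    color_shares: Mapping[str, float]
    age_band: str = ""
    artist_expertise: str = ""
    country: str = ""
    complications: bool = False

    def __post_init__(self) -> None:
        shape_area(self.shape_components)  # validates kinds/dimensions
        coverage_fraction_of(self.coverage_category)
        total = math.fsum(self.color_shares.values())
        if self.color_shares and abs(total - 1.0) > 1e-6:
            raise ValueError(f"color shares sum to {total}, expected 1")
        for color, share in self.color_shares.items():
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"color share for {color!r} outside [0, 1]: {share}")

    @property
    def area_cm2(self) -> float:
        return shape_area(self.shape_components)


@dataclass(frozen=True)
class ExposureEstimate:
    """Absolute tattooed-skin areas for one participant.

    ``coverage_fraction`` is None (undefined) when no tattooed area exists —
    never coerced to 0, which would bias agreement statistics.
    """

    participant_id: str
    total_area_cm2: float
    per_color_area_cm2: Mapping[str, float]
    per_part_area_cm2: Mapping[str, float]
    coverage_fraction: Optional[float]

    def __post_init__(self) -> None:
        for name, mapping in (
            ("per_color_area_cm2", self.per_color_area_cm2),
            ("per_part_area_cm2", self.per_part_area_cm2),
        ):
            subtotal = math.fsum(mapping.values())
            tol = 1e-6 * max(1.0, abs(self.total_area_cm2))
            if abs(subtotal - self.total_area_cm2) > tol:
                raise ValueError(
                    f"{name} sums to {subtotal}, expected total {self.total_area_cm2}"
                )
        if self.coverage_fraction is not None and not 0.0 <= self.coverage_fraction <= 1.0 + 1e-9:
            raise ValueError(f"coverage fraction outside [0, 1]: {self.coverage_fraction}")

    def colored_area_cm2(self) -> float:
        """Total area of all non-black/gray canonical colors."""
        return math.fsum(
            a for c, a in self.per_color_area_cm2.items() if ColorScheme.is_colored(c)
        )

    def black_gray_area_cm2(self) -> float:
        return self.per_color_area_cm2.get("black_gray", 0.0)


def coverage_weighted(
    areas: Sequence[float], coverage_props: Sequence[float], denominator: float
) -> float:
    """Area-weighted coverage: Σ(areaᵢ × propᵢ) / denominator."""
    if len(areas) != len(coverage_props):
        raise ValueError("areas and coverage_props must have the same length")
    if denominator <= 0:
        raise CoverageError(f"coverage denominator must be positive, got {denominator}")
    return math.fsum(a * p for a, p in zip(areas, coverage_props)) / denominator


def _assemble(
    participant_id: str,
    part_color_areas: Mapping[tuple[str, str], float],
    coverage: Optional[float],
) -> ExposureEstimate:
    per_color: dict[str, float] = {}
    per_part: dict[str, float] = {}
    for (part, color), area in part_color_areas.items():
        per_color[color] = per_color.get(color, 0.0) + area
        per_part[part] = per_part.get(part, 0.0) + area
    total = math.fsum(part_color_areas.values())
    return ExposureEstimate(
        participant_id=participant_id,
        total_area_cm2=total,
        per_color_area_cm2=per_color,
        per_part_area_cm2=per_part,
        coverage_fraction=coverage,
    )


def _coverage_from_entries(
    report: SelfReport, per_part_area: Mapping[str, float]
) -> Optional[float]:
    """Self-report coverage as the area-weighted mean of per-part categories."""
    weights, props = [], []
    for part, cat in report.coverage_entries:
        area = per_part_area.get(part, 0.0)
        if area > 0:
            weights.append(area)
            props.append(coverage_fraction_of(cat))
    denom = math.fsum(weights)
    if denom <= 0:
        return None
    return coverage_weighted(weights, props, denom)


def convert_unit_report(
    report: SelfReport,
    unit_area_cm2: float,
    color_scheme: ColorScheme = DEFAULT_COLOR_SCHEME,
) -> ExposureEstimate:
    """Convert a hand-surface or credit-card report into absolute areas.

    Each (part, color) magnitude is multiplied by the unit area (the
    respondent's measured hand, or the 30 cm² credit-card constant) and
    aggregated through the canonical color scheme.
    """
    if report.dialect not in ("hand_surface", "credit_card"):
        raise ValueError(f"convert_unit_report got dialect {report.dialect!r}")
    if unit_area_cm2 <= 0:
        raise ValueError(f"unit area must be positive, got {unit_area_cm2}")
    part_color: dict[tuple[str, str], float] = {}
    for part, color, magnitude in report.entries:
        canonical = color_scheme.canonical(color)
        key = (part, canonical)
        part_color[key] = part_color.get(key, 0.0) + magnitude * unit_area_cm2
    per_part: dict[str, float] = {}
    for (part, _), area in part_color.items():
        per_part[part] = per_part.get(part, 0.0) + area
    coverage = _coverage_from_entries(report, per_part)
    return _assemble(report.participant_id, part_color, coverage)


def convert_scheme_report(
    report: SelfReport,
    part_areas_cm2: Mapping[str, float],
    color_scheme: ColorScheme = DEFAULT_COLOR_SCHEME,
) -> ExposureEstimate:
    """Convert a body-schemes report into absolute areas.

    The tattooed area of each part is the part's skin area times the chosen
    scenario fraction; it is split across colors in proportion to the
    (normalized) per-color Likert fractions, so per-color areas sum exactly
    to the part total.
    """
    if report.dialect != "body_schemes":
        raise ValueError(f"convert_scheme_report got dialect {report.dialect!r}")
    scenario: dict[str, float] = {}
    for part, cat in report.scenario_entries:
        if part not in part_areas_cm2:
            raise UnknownBodyPartError(
                f"body part {part!r} not present in derived part areas"
            )
        scenario[part] = coverage_fraction_of(cat)
    color_weights: dict[str, dict[str, float]] = {}
    for part, color, likert in report.entries:
        if part not in part_areas_cm2:
            raise UnknownBodyPartError(
                f"body part {part!r} not present in derived part areas"
            )
        canonical = color_scheme.canonical(color)
        bucket = color_weights.setdefault(part, {})
        bucket[canonical] = bucket.get(canonical, 0.0) + likert
    part_color: dict[tuple[str, str], float] = {}
    for part, frac in scenario.items():
        tattooed = part_areas_cm2[part] * frac
        weights = color_weights.get(part)
        if not weights:
            # scenario without color detail: attribute to 'other'
            part_color[(part, "other")] = part_color.get((part, "other"), 0.0) + tattooed
            continue
        wsum = math.fsum(weights.values())
        for canonical, w in weights.items():
            key = (part, canonical)
            part_color[key] = part_color.get(key, 0.0) + tattooed * (w / wsum)
    per_part = {p: part_areas_cm2[p] * f for p, f in scenario.items()}
    coverage = _coverage_from_entries(report, per_part)
    return _assemble(report.participant_id, part_color, coverage)


def validation_exposure(
    records: Iterable[TattooRecord],
    color_scheme: ColorScheme = DEFAULT_COLOR_SCHEME,
) -> ExposureEstimate:
    """Aggregate measured tattoos into one participant-level estimate.

    Total = Σ shape areas; per-color = Σ area × share (through the canonical
    scheme); coverage = area-weighted mean of per-tattoo coverage fractions.
    """
    records = list(records)
    pids = {r.participant_id for r in records}
    if len(pids) > 1:
        raise ValueError(f"records span multiple participants: {sorted(pids)}")
    pid = records[0].participant_id if records else ""
    if not records:
        return ExposureEstimate(pid, 0.0, {}, {}, None)
    part_color: dict[tuple[str, str], float] = {}
    areas, props = [], []
    for rec in records:
        area = rec.area_cm2
        areas.append(area)
        props.append(coverage_fraction_of(rec.coverage_category))
        shares = rec.color_shares or {"other": 1.0}
        for color, share in shares.items():
            canonical = color_scheme.canonical(color)
            key = (rec.body_part, canonical)
            part_color[key] = part_color.get(key, 0.0) + area * share
    total = math.fsum(areas)
    coverage = coverage_weighted(areas, props, total) if total > 0 else None
    return _assemble(pid, part_color, coverage)
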