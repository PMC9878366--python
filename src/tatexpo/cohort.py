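"""Synthetic cohorts with the reporting-bias structure of tattoo self-report.

The generator produces participants (anthropometrics, hand measurements),
their "true" tattoo configurations (validated records with geometric shapes,
placement, color composition and coverage), and self-reports in any of the
three questionnaire dialects distorted by a configurable bias model:

* a multiplicative log-normal error on each reported (body part, color)
  area whose median is ``b0 · size^(−γ)`` — γ > 0 makes small tattoos
  relatively more overestimated, the pattern seen in real self-reports;
* randomized (mean-unbiased) rounding of magnitudes to the dialect's
  reporting grid — half-unit steps for the hand/credit-card units, the
  {0, 10, 25, 50, 75, 100} % scenario categories for body schemes;
* a category-confusion matrix on the coverage Likert scale;
* a probability of misreporting gray shading as black.

Every cohort satisfies the ingest invariants of the exposure engine, and
``recover_bias`` closes the loop by re-estimating (b0, γ) from paired
self-report/validation totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Optional, Sequence

import numpy as np

from .anthropometry import (
    BodyPartition,
    DEFAULT_HAND_FALLBACK_CM2,
    ParticipantProfile,
    body_part_areas,
    hand_unit_area,
)
from .exposure import (
    CREDIT_CARD_AREA_CM2,
    COVERAGE_CATEGORIES,
    SCENARIO_FRACTIONS,
    SelfReport,
    TattooRecord,
    coverage_fraction_of,
)

_COLORED_RAW = ("red", "orange", "yellow", "green", "blue", "violet", "pink", "brown", "white")
_AGE_BANDS = ("<1", "1-<5", "5-<10", "10-<15", ">=15")
_EXPERTISE = ("studio", "experienced_elsewhere", "nonexperienced_home", "other")


class InvalidSpecError(ValueError):
    """Cohort specification violates its invariants."""


class InsufficientPairsError(ValueError):
    """Too few usable self-report/validation pairs for bias recovery."""


def _check_probs(name: str, probs: Mapping, tol: float = 1e-9) -> None:
    total = math.fsum(probs.values())
    if abs(total - 1.0) > tol:
        raise InvalidSpecError(f"{name} probabilities sum to {total}, expected 1")
    if any(p < 0 for p in probs.values()):
        raise InvalidSpecError(f"{name} has negative probabilities")


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the generator.

    Defaults emulate the validation study's marginals: roughly two-thirds
    women in their twenties, a median of ~5 tattoos per person (IQR ~2-9),
    left-skewed log-normal tattoo sizes with median ~49 cm², black/gray
    dominant ink, and coverage on the five-category scale.
    """

    n_participants: int = 97
    seed: int = 0
    female_fraction: float = 0.68
    height_mean_cm: Mapping[str, float] = field(
        default_factory=lambda: {"female": 164.5, "male": 177.5}
    )
    height_sd_cm: float = 7.0
    weight_mean_kg: Mapping[str, float] = field(
        default_factory=lambda: {"female": 66.0, "male": 80.0}
    )
    weight_sd_kg: float = 12.0
    hand_measured_prob: float = 0.78
    # tattoo count: negative binomial (size r, mean m), resampled to >= 1
    tattoo_count_r: float = 1.5
    tattoo_count_mean: float = 6.0
    # per-tattoo area: log-normal on cm²
    size_log_mu: float = 3.9
    size_log_sigma: float = 1.5
    placement_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "head_neck": 0.03,
            "left_arm": 0.20,
            "right_arm": 0.20,
            "anterior_trunk": 0.13,
            "posterior_trunk": 0.19,
            "left_leg": 0.12,
            "right_leg": 0.12,
            "perineum": 0.01,
        }
    )
    # participant-level palette: all-black / black+gray shading / colored
    palette_probs: Mapping[str, float] = field(
        default_factory=lambda: {"black": 0.23, "gray": 0.25, "colored": 0.52}
    )
    coverage_probs: Mapping[int, float] = field(
        default_factory=lambda: {10: 0.15, 25: 0.20, 50: 0.30, 75: 0.20, 100: 0.15}
    )
    age_band_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "<1": 0.25,
            "1-<5": 0.45,
            "5-<10": 0.20,
            "10-<15": 0.07,
            ">=15": 0.03,
        }
    )
    expertise_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "studio": 0.80,
            "experienced_elsewhere": 0.12,
            "nonexperienced_home": 0.07,
            "other": 0.01,
        }
    )
    foreign_prob: float = 0.10
    complication_prob: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        """Load a spec from a YAML mapping of field name → value.

        Unspecified fields keep their defaults; the coverage mapping's keys
        are coerced to the integer category labels.
        """
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidSpecError(f"{path}: expected a mapping of spec fields")
        unknown = set(data) - {f.name for f in dc_fields(cls)}
        if unknown:
            raise InvalidSpecError(f"{path}: unknown spec fields {sorted(unknown)}")
        if "coverage_probs" in data:
            data["coverage_probs"] = {int(k): float(v) for k, v in data["coverage_probs"].items()}
        spec = cls(**data)
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.n_participants < 1:
            raise InvalidSpecError("n_participants must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise InvalidSpecError("female_fraction must be in [0, 1]")
        for scale, name in (
            (self.height_sd_cm, "height_sd_cm"),
            (self.weight_sd_kg, "weight_sd_kg"),
            (self.size_log_sigma, "size_log_sigma"),
            (self.tattoo_count_r, "tattoo_count_r"),
            (self.tattoo_count_mean, "tattoo_count_mean"),
        ):
            if scale <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        _check_probs("placement", self.placement_probs)
        _check_probs("palette", self.palette_probs)
        _check_probs("coverage", self.coverage_probs)
        _check_probs("age_band", self.age_band_probs)
        _check_probs("expertise", self.expertise_probs)
        if set(self.coverage_probs) != set(COVERAGE_CATEGORIES):
            raise InvalidSpecError(
                f"coverage categories must be exactly {COVERAGE_CATEGORIES}"
            )


@dataclass(frozen=True)
class BiasModel:
    """Dialect-independent reporting-bias parameters.

    The multiplicative factor applied to a true (part, color) area ``a`` is
    log-normal with median ``b0 · a^(−gamma)`` and log-scale sd ``sigma_b``.
    ``coverage_confusion`` is a 5×5 row-stochastic matrix over the coverage
    categories (true row → reported column). ``gray_to_black_prob`` is the
    per-participant probability of reporting gray shading as black.
    ``unit_grid_step`` is the reporting grid, in units, of the hand/credit
    dialects (0.5 = respondents answer in half units).
    """

    b0: float = 1.0
    gamma: float = 0.0
    sigma_b: float = 0.0
    coverage_confusion: tuple[tuple[float, ...], ...] = tuple(
        tuple(1.0 if i == j else 0.0 for j in range(5)) for i in range(5)
    )
    gray_to_black_prob: float = 0.0
    unit_grid_step: float = 0.5

    def validate(self) -> None:
        if self.b0 <= 0:
            raise InvalidSpecError("b0 must be positive")
        if self.gamma < 0:
            raise InvalidSpecError("gamma must be >= 0")
        if self.sigma_b < 0:
            raise InvalidSpecError("sigma_b must be >= 0")
        if self.unit_grid_step <= 0:
            raise InvalidSpecError("unit_grid_step must be positive")
        mat = np.asarray(self.coverage_confusion, dtype=float)
        if mat.shape != (5, 5) or np.any(mat < 0) or np.any(np.abs(mat.sum(axis=1) - 1) > 1e-9):
            raise InvalidSpecError("coverage_confusion must be 5x5 row-stochastic")
        if not 0.0 <= self.gray_to_black_prob <= 1.0:
            raise InvalidSpecError("gray_to_black_prob must be in [0, 1]")

    @classmethod
    def null(cls) -> "BiasModel":
        """Identity bias: quantization is the only reporting error."""
        return cls()

    @classmethod
    def default_study(cls) -> "BiasModel":
        """Size-dependent overestimation resembling real self-reports.

        Median factor 2 at a 49 cm² (median-sized) entry with γ = 0.25, so
        small tattoos are relatively more overestimated while large areas
        still carry the largest absolute overestimation; upward coverage
        confusion calibrated to a ~5 percentage-point systematic coverage
        overestimate; a 30 % chance of calling gray "black".
        """
        confusion = []
        for i in range(5):
            row = [0.0] * 5
            row[i] = 0.65
            row[min(i + 1, 4)] += 0.30
            row[max(i - 1, 0)] += 0.05
            confusion.append(tuple(row))
        return cls(
            b0=2.0 * 49.0**0.25,
            gamma=0.25,
            sigma_b=0.5,
            coverage_confusion=tuple(confusion),
            gray_to_black_prob=0.30,
        )


# --------------------------------------------------------------------------
# cohort generation


def _participant_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    # fixed-key sub-streams: regenerating participant i is stable regardless
    # of cohort size or call order
    return np.random.default_rng(np.random.SeedSequence([seed, index, stream]))


def _draw_truncated(rng, mean, sd, lo, hi) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(min(max(mean, lo + 1e-6), hi - 1e-6))


def _draw_count(rng, r: float, mean: float) -> int:
    p = r / (r + mean)
    for _ in range(1000):
        k = int(rng.negative_binomial(r, p))
        if k >= 1:
            return k
    return 1


def _shape_for_area(rng, area: float) -> tuple[str, tuple[float, ...]]:
    kind = rng.choice(["circle", "rectangle", "oval", "square"], p=[0.3, 0.3, 0.3, 0.1])
    if kind == "circle":
        return "circle", (math.sqrt(area / math.pi),)
    if kind == "square":
        return "square", (math.sqrt(area),)
    aspect = rng.uniform(1.0, 3.0)
    if kind == "rectangle":
        w = math.sqrt(area / aspect)
        return "rectangle", (aspect * w, w)
    r2 = math.sqrt(area / (math.pi * aspect))
    return "oval", (aspect * r2, r2)


def _tattoo_colors(rng, palette: str, force_colored: bool) -> dict[str, float]:
    if palette == "black":
        return {"black": 1.0}
    if palette == "gray":
        u = float(rng.uniform(0.2, 0.7))
        return {"black": u, "gray": 1.0 - u}
    if not force_colored and rng.random() < 0.3:
        return {"black": 1.0}
    base_black = float(rng.uniform(0.1, 0.5))
    n_colors = int(rng.integers(1, 4))
    chosen = rng.choice(len(_COLORED_RAW), size=n_colors, replace=False)
    weights = rng.dirichlet(np.ones(n_colors))
    shares = {"black": base_black}
    for idx, w in zip(chosen, weights):
        label = _COLORED_RAW[int(idx)]
        shares[label] = shares.get(label, 0.0) + float(w) * (1.0 - base_black)
    total = math.fsum(shares.values())
    return {c: s / total for c, s in shares.items()}


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[ParticipantProfile], list[TattooRecord]]:
    """Draw a cohort of participants and their true (validated) tattoos.

    Reproducible given ``spec.seed``; participant i is generated from a
    dedicated sub-stream keyed by (seed, i).
    """
    spec.validate()
    parts = tuple(spec.placement_probs)
    part_p = np.asarray([spec.placement_probs[p] for p in parts], dtype=float)
    cov_cats = tuple(sorted(spec.coverage_probs))
    cov_p = np.asarray([spec.coverage_probs[c] for c in cov_cats], dtype=float)
    palettes = tuple(spec.palette_probs)
    pal_p = np.asarray([spec.palette_probs[p] for p in palettes], dtype=float)
    bands = tuple(spec.age_band_probs)
    band_p = np.asarray([spec.age_band_probs[b] for b in bands], dtype=float)
    experts = tuple(spec.expertise_probs)
    exp_p = np.asarray([spec.expertise_probs[e] for e in experts], dtype=float)

    participants: list[ParticipantProfile] = []
    records: list[TattooRecord] = []
    for i in range(spec.n_participants):
        rng = _participant_rng(spec.seed, i)
        pid = f"P{i:04d}"
        sex = "female" if rng.random() < spec.female_fraction else "male"
        height = _draw_truncated(rng, spec.height_mean_cm[sex], spec.height_sd_cm, 120, 220)
        weight = _draw_truncated(rng, spec.weight_mean_kg[sex], spec.weight_sd_kg, 35, 180)
        if rng.random() < spec.hand_measured_prob:
            hand_l = _draw_truncated(rng, 17.2 if sex == "female" else 19.0, 1.0, 13, 24)
            hand_w = _draw_truncated(rng, 8.2 if sex == "female" else 9.2, 0.6, 6, 12)
        else:
            hand_l = hand_w = None
        participants.append(
            ParticipantProfile(
                participant_id=pid,
                sex=sex,
                height_cm=round(height, 1),
                weight_kg=round(weight, 1),
                hand_length_cm=None if hand_l is None else round(hand_l, 1),
                hand_width_cm=None if hand_w is None else round(hand_w, 1),
            )
        )
        palette = palettes[int(rng.choice(len(palettes), p=pal_p))]
        n_tat = _draw_count(rng, spec.tattoo_count_r, spec.tattoo_count_mean)
        # tattoos must fit on skin: track remaining capacity per body part
        # (at most 95 % of a part's skin area can be inked)
        part_skin = body_part_areas(participants[-1])
        remaining = {p: 0.95 * part_skin.get(p, 0.0) for p in parts}
        for j in range(n_tat):
            part = parts[int(rng.choice(len(parts), p=part_p))]
            for _ in range(10):
                if remaining[part] >= 5.0:
                    break
                part = parts[int(rng.choice(len(parts), p=part_p))]
            area = float(rng.lognormal(spec.size_log_mu, spec.size_log_sigma))
            area = min(area, remaining[part])
            if area < 1.0:
                continue
            remaining[part] -= area
            kind, dims = _shape_for_area(rng, area)
            records.append(
                TattooRecord(
                    participant_id=pid,
                    tattoo_id=f"{pid}-T{j:02d}",
                    body_part=part,
                    shape_components=((kind, dims),),
                    coverage_category=int(cov_cats[int(rng.choice(len(cov_cats), p=cov_p))]),
                    color_shares=_tattoo_colors(rng, palette, force_colored=(j == 0)),
                    age_band=bands[int(rng.choice(len(bands), p=band_p))],
                    artist_expertise=experts[int(rng.choice(len(experts), p=exp_p))],
                    country="other" if rng.random() < spec.foreign_prob else "France",
                    complications=bool(rng.random() < spec.complication_prob),
                )
            )
    return participants, records


# --------------------------------------------------------------------------
# reporting bias


def _rand_round_grid(x: float, step: float, rng) -> float:
    """Round x to the grid {0, step, 2·step, ...}, unbiased in expectation."""
    k = math.floor(x / step)
    frac = x / step - k
    if rng.random() < frac:
        k += 1
    return k * step


def _rand_round_levels(x: float, levels: Sequence[float], rng) -> float:
    """Round x to the sorted grid ``levels``, unbiased between neighbors."""
    if x <= levels[0]:
        return levels[0]
    if x >= levels[-1]:
        return levels[-1]
    for lo, hi in zip(levels, levels[1:]):
        if lo <= x <= hi:
            if rng.random() < (x - lo) / (hi - lo):
                return hi
            return lo
    return levels[-1]  # pragma: no cover


def _nearest_level(x: float, levels: Sequence[float]) -> float:
    return min(levels, key=lambda lv: abs(lv - x))


_SCENARIO_LEVELS = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0)
_LIKERT_LEVELS = (0.1, 0.25, 0.5, 0.75, 1.0)
_FRACTION_TO_CATEGORY = {0.1: 10, 0.25: 25, 0.5: 50, 0.75: 75, 1.0: 100}


def true_part_color_areas(
    records: Sequence[TattooRecord],
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """(part, raw color) → cm² and part → coverage fraction, from true records."""
    cells: dict[tuple[str, str], float] = {}
    cov_num: dict[str, float] = {}
    cov_den: dict[str, float] = {}
    for rec in records:
        area = rec.area_cm2
        for color, share in rec.color_shares.items():
            key = (rec.body_part, color)
            cells[key] = cells.get(key, 0.0) + area * share
        cov_num[rec.body_part] = cov_num.get(rec.body_part, 0.0) + area * coverage_fraction_of(
            rec.coverage_category
        )
        cov_den[rec.body_part] = cov_den.get(rec.body_part, 0.0) + area
    coverage = {p: cov_num[p] / cov_den[p] for p in cov_den if cov_den[p] > 0}
    return cells, coverage


def apply_reporting_bias(
    participants: Sequence[ParticipantProfile],
    records: Sequence[TattooRecord],
    model: BiasModel,
    dialect: str,
    seed: int,
    partition: Optional[BodyPartition] = None,
    hand_fallback_cm2: float = DEFAULT_HAND_FALLBACK_CM2,
    quantize: bool = True,
) -> list[SelfReport]:
    """Distort true tattoo configurations into self-reports in one dialect.

    Per (body part, color) cell the true area is multiplied by a log-normal
    factor with median ``b0 · area^(−γ)``, then expressed in the dialect's
    unit and rounded to its reporting grid by randomized (mean-unbiased)
    rounding. Coverage categories pass through the confusion matrix; gray is
    relabeled black with the model's probability. ``quantize=False`` skips
    grid rounding of the hand/credit unit counts (continuum limit).
    """
    model.validate()
    if partition is None:
        partition = BodyPartition.default()
    by_pid: dict[str, list[TattooRecord]] = {}
    for rec in records:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    reports: list[SelfReport] = []
    for i, prof in enumerate(participants):
        rng = _participant_rng(seed, i, stream=101)
        recs = by_pid.get(prof.participant_id, [])
        cells, coverage = true_part_color_areas(recs)
        # multiplicative size-dependent bias per cell
        biased: dict[tuple[str, str], float] = {}
        for (part, color), area in cells.items():
            if area <= 0:
                continue
            log_median = math.log(model.b0) - model.gamma * math.log(area)
            factor = math.exp(log_median + model.sigma_b * rng.standard_normal())
            biased[(part, color)] = area * factor
        # gray -> black misreport (raw labels; canonical analysis merges anyway)
        if model.gray_to_black_prob > 0 and rng.random() < model.gray_to_black_prob:
            relabeled: dict[tuple[str, str], float] = {}
            for (part, color), area in biased.items():
                key = (part, "black") if color in ("gray", "grey", "gray_wash") else (part, color)
                relabeled[key] = relabeled.get(key, 0.0) + area
            biased = relabeled
        part_totals: dict[str, float] = {}
        for (part, _), area in biased.items():
            part_totals[part] = part_totals.get(part, 0.0) + area

        entries: list[tuple[str, str, float]] = []
        scenario_entries: list[tuple[str, int]] = []
        if dialect in ("hand_surface", "credit_card"):
            unit = (
                hand_unit_area(prof, hand_fallback_cm2)
                if dialect == "hand_surface"
                else CREDIT_CARD_AREA_CM2
            )
            for (part, color), area in sorted(biased.items()):
                mag = area / unit
                if quantize:
                    mag = _rand_round_grid(mag, model.unit_grid_step, rng)
                if mag > 0:
                    entries.append((part, color, mag))
            reported_parts = {part for part, _, _ in entries}
        elif dialect == "body_schemes":
            part_areas = body_part_areas(prof, partition)
            reported_parts = set()
            for part in sorted(part_totals):
                frac = min(part_totals[part] / part_areas[part], 1.0)
                level = _rand_round_levels(frac, _SCENARIO_LEVELS, rng)
                if level <= 0:
                    continue
                reported_parts.add(part)
                scenario_entries.append((part, _FRACTION_TO_CATEGORY[level]))
                for (p2, color), area in sorted(biased.items()):
                    if p2 != part:
                        continue
                    share = area / part_totals[part]
                    likert = _nearest_level(share, _LIKERT_LEVELS)
                    entries.append((part, color, likert))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")

        coverage_entries: list[tuple[str, int]] = []
        confusion = np.asarray(model.coverage_confusion, dtype=float)
        cov_levels = [cf / 100 for cf in COVERAGE_CATEGORIES]
        for part in sorted(reported_parts):
            if part not in coverage:
                continue
            true_idx = int(np.argmin([abs(lv - coverage[part]) for lv in cov_levels]))
            rep_idx = int(rng.choice(5, p=confusion[true_idx]))
            coverage_entries.append((part, COVERAGE_CATEGORIES[rep_idx]))

        reports.append(
            SelfReport(
                participant_id=prof.participant_id,
                dialect=dialect,
                entries=tuple(entries),
                coverage_entries=tuple(coverage_entries),
                scenario_entries=tuple(scenario_entries),
            )
        )
    return reports


# --------------------------------------------------------------------------
# bias recovery


@dataclass(frozen=True)
class BiasRecovery:
    """Estimated bias parameters from paired totals.

    ``b0`` is the median multiplicative factor at ``reference_size_cm2`` (the
    sample's geometric-mean validated size); when γ = 0 it equals the
    model's size-independent b0. ``b0_at_unit`` extrapolates to 1 cm² for
    direct comparison with a size-1-referenced model (unstable when γ is
    imprecise).
    """

    b0: float
    gamma: float
    reference_size_cm2: float
    n_used: int
    n_excluded: int

    @property
    def b0_at_unit(self) -> float:
        return self.b0 * self.reference_size_cm2**self.gamma


def recover_bias(
    self_totals: Mapping[str, float],
    validation_totals: Mapping[str, float],
    min_pairs: int = 50,
) -> BiasRecovery:
    """Estimate (b0, γ) by regressing log(self/validation) on log(validation).

    The bias model implies E[log(self/validation)] = log b0 − γ·log(size),
    so the OLS slope is −γ. The regressor is centered at the geometric-mean
    validated size, so the intercept estimates the median factor at that
    reference size without long extrapolation. Pairs with a non-positive
    total on either side are excluded (their count is reported).
    """
    ids = sorted(set(self_totals) & set(validation_totals))
    pairs = [(self_totals[i], validation_totals[i]) for i in ids]
    usable = [(s, v) for s, v in pairs if s > 0 and v > 0]
    n_excluded = len(pairs) - len(usable)
    if len(usable) < min_pairs:
        raise InsufficientPairsError(
            f"need >= {min_pairs} usable pairs, got {len(usable)}"
        )
    s = np.asarray([u[0] for u in usable], dtype=float)
    v = np.asarray([u[1] for u in usable], dtype=float)
    log_ratio = np.log(s / v)
    log_size = np.log(v)
    center = float(log_size.mean())
    slope, intercept = np.polyfit(log_size - center, log_ratio, 1)
    return BiasRecovery(
        b0=float(np.exp(intercept)),
        gamma=float(-slope),
        reference_size_cm2=float(np.exp(center)),
        n_used=len(usable),
        n_excluded=n_excluded,
    )
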