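"""Body surface area and body partitioning.

Total body surface area (BSA) is derived from sex-stratified Schlich
power-law formulas of weight (kg) and height (cm), yielding m². Per-body-part
skin areas follow from a rule-of-nines partition (the burn-medicine
convention) expressed as fractions of total BSA; the partition is
configurable through a YAML mapping so alternative partitions can be swapped
in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import yaml

#: sex -> (coefficient, weight exponent, height exponent); BSA in m².
SCHLICH_CONSTANTS: dict[str, tuple[float, float, float]] = {
    "female": (0.000975482, 0.46, 1.08),
    "male": (0.000579479, 0.38, 1.24),
}

#: Standard rule-of-nines fractions of total body surface area.
DEFAULT_PARTITION_FRACTIONS: dict[str, float] = {
    "head_neck": 0.09,
    "left_arm": 0.09,
    "right_arm": 0.09,
    "anterior_trunk": 0.18,
    "posterior_trunk": 0.18,
    "left_leg": 0.18,
    "right_leg": 0.18,
    "perineum": 0.01,
}

#: Surgical-mask reference rectangle (17.5 cm x 9.5 cm) used when a
#: respondent could not measure their hand with a ruler.
DEFAULT_HAND_FALLBACK_CM2: float = 17.5 * 9.5


class UnknownSexError(ValueError):
    """Sex label outside the {female, male} vocabulary."""


class UnknownBodyPartError(KeyError):
    """A body-part label is missing from the partition vocabulary."""


class MissingHandDataError(ValueError):
    """Neither measured hand dimensions nor a fallback area are available."""


@dataclass(frozen=True)
class ParticipantProfile:
    """Anthropometric anchor for one respondent.

    ``hand_length_cm``/``hand_width_cm`` are the ruler measurements of the
    respondent's hand (both present or both absent).
    """

    participant_id: str
    sex: str
    height_cm: float
    weight_kg: float
    hand_length_cm: Optional[float] = None
    hand_width_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in SCHLICH_CONSTANTS:
            raise UnknownSexError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not 50.0 < self.height_cm < 250.0:
            raise ValueError(f"height {self.height_cm} cm outside plausible (50, 250)")
        if not 20.0 < self.weight_kg < 300.0:
            raise ValueError(f"weight {self.weight_kg} kg outside plausible (20, 300)")
        if (self.hand_length_cm is None) != (self.hand_width_cm is None):
            raise ValueError("hand_length_cm and hand_width_cm must both be present or both absent")
        if self.hand_length_cm is not None:
            if self.hand_length_cm <= 0 or self.hand_width_cm <= 0:  # type: ignore[operator]
                raise ValueError("hand dimensions must be positive")


@dataclass(frozen=True)
class BodyPartition:
    """Fractions of total body surface per body-part label.

    Fractions must lie in (0, 1] and sum to 1 (±1e-9); the labels are the
    controlled vocabulary shared by the whole pipeline.
    """

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("partition has no parts")
        for part, frac in self.fractions.items():
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"fraction for {part!r} must be in (0, 1], got {frac}")
        total = math.fsum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"partition fractions sum to {total}, expected 1")

    def fraction(self, part: str) -> float:
        try:
            return self.fractions[part]
        except KeyError:
            raise UnknownBodyPartError(
                f"unknown body part {part!r}; known: {sorted(self.fractions)}"
            ) from None

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(self.fractions)

    @classmethod
    def default(cls) -> "BodyPartition":
        return cls(dict(DEFAULT_PARTITION_FRACTIONS))

    @classmethod
    def from_yaml(cls, path) -> "BodyPartition":
        """Load a partition from a YAML mapping ``{part_label: fraction}``."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of part -> fraction")
        return cls({str(k): float(v) for k, v in data.items()})


def bsa_schlich(sex: str, weight_kg: float, height_cm: float) -> float:
    """Total body surface area in m² from the sex-stratified power laws.

    female: 0.000975482 · w^0.46 · h^1.08
    male:   0.000579479 · w^0.38 · h^1.24
    """
    try:
        coeff, a, b = SCHLICH_CONSTANTS[sex]
    except KeyError:
        raise UnknownSexError(f"sex must be 'female' or 'male', got {sex!r}") from None
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return coeff * weight_kg**a * height_cm**b


def body_part_areas(
    profile: ParticipantProfile, partition: Optional[BodyPartition] = None
) -> dict[str, float]:
    """Skin area in cm² per body part: BSA(m²) × 10⁴ × part fraction."""
    if partition is None:
        partition = BodyPartition.default()
    total_cm2 = bsa_schlich(profile.sex, profile.weight_kg, profile.height_cm) * 1e4
    return {part: total_cm2 * frac for part, frac in partition.fractions.items()}


def hand_unit_area(
    profile: ParticipantProfile, fallback_cm2: Optional[float] = None
) -> float:
    """Area of the respondent's hand unit in cm² (length × width).

    Falls back to ``fallback_cm2`` when the hand was not measured; raises
    :class:`MissingHandDataError` when neither is available.
    """
    if profile.hand_length_cm is not None and profile.hand_width_cm is not None:
        return profile.hand_length_cm * profile.hand_width_cm
    if fallback_cm2 is not None:
        if fallback_cm2 <= 0:
            raise ValueError("fallback hand area must be positive")
        return fallback_cm2
    raise MissingHandDataError(
        f"participant {profile.participant_id}: no hand dimensions and no fallback area"
    )
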