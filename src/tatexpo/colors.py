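"""Canonical tattoo-ink color vocabulary and raw-label mapping.

Analyses group ink colors into a small canonical set. Black and gray (incl.
gray wash, i.e. diluted black used for shading) are merged into a single
``black_gray`` class because respondents very frequently report gray shading
as black; every other color, including white, counts as "colored".
"""

from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL_COLORS: tuple[str, ...] = (
    "black_gray",
    "red",
    "orange_yellow",
    "green",
    "blue",
    "violet_pink",
    "brown",
    "white",
    "other",
)

#: Raw questionnaire / validation-sheet labels -> canonical class.
DEFAULT_COLOR_MAP: dict[str, str] = {
    "black": "black_gray",
    "gray": "black_gray",
    "grey": "black_gray",
    "gray_wash": "black_gray",
    "black_gray": "black_gray",
    "red": "red",
    "orange": "orange_yellow",
    "yellow": "orange_yellow",
    "orange_yellow": "orange_yellow",
    "green": "green",
    "blue": "blue",
    "violet": "violet_pink",
    "purple": "violet_pink",
    "pink": "violet_pink",
    "violet_pink": "violet_pink",
    "brown": "brown",
    "white": "white",
    "other": "other",
}


class UnknownColorError(KeyError):
    """An input color label is not in the scheme's vocabulary."""


@dataclass(frozen=True)
class ColorScheme:
    """Maps raw color labels onto the canonical analysis classes."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLOR_MAP))

    def canonical(self, label: str) -> str:
        key = label.strip().lower()
        try:
            return self.mapping[key]
        except KeyError:
            raise UnknownColorError(
                f"unknown color label {label!r}; known: {sorted(self.mapping)}"
            ) from None

    @staticmethod
    def is_colored(canonical: str) -> bool:
        """True for any canonical class other than black/gray.

        White ink counts as colored, matching the convention that a
        participant is "colored" if any ink other than black or gray is
        present.
        """
        return canonical != "black_gray"


DEFAULT_COLOR_SCHEME = ColorScheme()
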