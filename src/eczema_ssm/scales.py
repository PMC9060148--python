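"""Bounded atopic-dermatitis severity scales.

Each composite severity score is a continuous-valued instrument with a fixed
range: EASI in [0, 72], oSCORAD in [0, 83], SCORAD in [0, 103] and POEM in
[0, 28].  The maximum ``M`` enters the measurement model as the upper
truncation bound of the observation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SeverityScale", "SCALES", "get_scale"]


@dataclass(frozen=True)
class SeverityScale:
    """A named severity score bounded on ``[0, max_score]``."""

    name: str
    max_score: float

    def __post_init__(self) -> None:
        if self.max_score <= 0:
            raise ValueError("max_score must be positive")

    def validate_value(self, value: float) -> None:
        if not 0.0 <= value <= self.max_score:
            raise ValueError(
                f"{self.name} value {value} outside [0, {self.max_score}]"
            )


SCALES: dict[str, SeverityScale] = {
    "EASI": SeverityScale("EASI", 72.0),
    "oSCORAD": SeverityScale("oSCORAD", 83.0),
    "SCORAD": SeverityScale("SCORAD", 103.0),
    "POEM": SeverityScale("POEM", 28.0),
}


def get_scale(name: str) -> SeverityScale:
    """Look up a severity scale by name (case-insensitive for convenience)."""
    key = {k.lower(): k for k in SCALES}.get(name.lower())
    if key is None:
        raise KeyError(f"unknown severity scale {name!r}; known: {sorted(SCALES)}")
    return SCALES[key]
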