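"""Confidence tiers for candidates, steps and pathways."""

from __future__ import annotations

import enum
import functools


@functools.total_ordering
class Confidence(enum.Enum):
    """Ordered confidence tier: LOW < MEDIUM < HIGH."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2

    def __lt__(self, other: "Confidence") -> bool:
        if not isinstance(other, Confidence):
            return NotImplemented
        return self.value < other.value

    def __str__(self) -> str:  # used in reports and TSVs
        return self.name.lower()

    @classmethod
    def from_string(cls, s: str) -> "Confidence":
        return cls[s.upper()]
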