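"""Kabat position bookkeeping for antibody variable domains.

Positions are labelled ``H30``, ``L89``, ``H100A`` etc.; insertion letters
order lexicographically after the bare number (100 < 100A < 100B < 101),
which is how variable-length CDR-H3 loops are accommodated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from string import ascii_uppercase

_LABEL_RE = re.compile(r"^([HL])(\d+)([A-Z]?)$")

# Kabat variable-domain numbering does not exceed ~113 (H) / ~109 (L)
_MAX_NUMBER = {"H": 113, "L": 109}


@total_ordering
@dataclass(frozen=True)
class KabatPosition:
    """One Kabat position on the heavy (H) or light (L) chain."""

    chain: str
    number: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.chain not in ("H", "L"):
            raise ValueError(f"chain must be 'H' or 'L', got {self.chain!r}")
        if not 1 <= self.number <= _MAX_NUMBER[self.chain]:
            raise ValueError(f"Kabat number {self.number} out of range for chain {self.chain}")
        if self.insertion and (len(self.insertion) != 1 or self.insertion not in ascii_uppercase):
            raise ValueError(f"insertion code must be a single letter, got {self.insertion!r}")

    @property
    def label(self) -> str:
        return f"{self.chain}{self.number}{self.insertion}"

    @classmethod
    def parse(cls, label: str) -> "KabatPosition":
        m = _LABEL_RE.match(label.strip().upper())
        if not m:
            raise ValueError(f"cannot parse Kabat label {label!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def _key(self) -> tuple:
        return (self.chain, self.number, self.insertion)

    def __lt__(self, other: "KabatPosition") -> bool:
        if not isinstance(other, KabatPosition):
            return NotImplemented
        return self._key() < other._key()


def h3_positions(length: int, max_length: int = 18) -> tuple[KabatPosition, ...]:
    """Kabat labels for a CDR-H3 of ``length`` residues over H95–H102.

    The eight base positions are 95..100, 101, 102. Shorter loops drop
    positions from 100 backwards; longer loops insert 100A, 100B, ... after
    100. Lengths needing insertion codes beyond Z are rejected (a loop of 18
    residues only reaches 100J).
    """
    if length < 1:
        raise ValueError("CDR-H3 length must be >= 1")
    if length > max_length:
        raise ValueError(f"CDR-H3 length {length} exceeds maximum {max_length}")
    if length - 8 > len(ascii_uppercase):
        raise ValueError("CDR-H3 too long for Kabat insertion codes")
    tail = [KabatPosition("H", 101), KabatPosition("H", 102)]
    if length <= 2:
        return tuple(tail[-length:])
    n_mid = length - 2
    mids = [KabatPosition("H", n) for n in range(95, 95 + min(n_mid, 6))]
    if n_mid > 6:
        mids += [KabatPosition("H", 100, letter) for letter in ascii_uppercase[: n_mid - 6]]
    return tuple(mids + tail)


def parse_positions(labels: list[str]) -> tuple[KabatPosition, ...]:
    positions = tuple(KabatPosition.parse(lbl) for lbl in labels)
    if list(positions) != sorted(positions):
        raise ValueError("Kabat positions must be given in increasing order")
    return positions
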