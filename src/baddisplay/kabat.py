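"""Kabat coordinates and framework/CDR region maps for antibody variable domains.

The Kabat scheme addresses each residue of a variable domain by a 1-based
number plus an optional insertion letter (e.g., 100A), so that structurally
equivalent positions carry the same address across antibodies.  Region maps
partition the coordinate range into the four framework regions (FR1-FR4) and
the three complementarity-determining regions (CDR1-3).
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from typing import Literal, Optional

from .errors import OutOfRangeError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ChainClass = Literal["heavy", "kappa", "lambda"]

REGION_LABELS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

_POSITION_RE = re.compile(r"^([HL]?)(\d+)([A-Z]?)$")


@functools.total_ordering
@dataclass(frozen=True)
class KabatPosition:
    """A Kabat coordinate: positive number plus optional insertion letter.

    Ordering is (number, insertion) with an absent insertion sorting before
    'A', so 100 < 100A < 100B < 101.
    """

    number: int
    insertion: Optional[str] = None

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"Kabat number must be >= 1, got {self.number}")
        if self.insertion is not None:
            if len(self.insertion) != 1 or not "A" <= self.insertion <= "Z":
                raise ValueError(f"insertion code must be A-Z, got {self.insertion!r}")

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.number, self.insertion or "")

    def __lt__(self, other: "KabatPosition") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return f"{self.number}{self.insertion or ''}"

    @classmethod
    def parse(cls, text: str) -> "KabatPosition":
        """Parse '4', '100A', or a chain-prefixed form like 'L4' / 'H35B'."""
        m = _POSITION_RE.match(text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse Kabat position {text!r}")
        return cls(int(m.group(2)), m.group(3) or None)


@dataclass(frozen=True)
class RegionMap:
    """Ordered FR/CDR boundaries partitioning a chain's Kabat range."""

    chain_class: ChainClass
    boundaries: tuple[tuple[str, KabatPosition, KabatPosition], ...] = field(default=())

    def __post_init__(self) -> None:
        labels = tuple(label for label, _, _ in self.boundaries)
        if labels != REGION_LABELS[: len(labels)]:
            raise ValueError(f"regions must appear in order {REGION_LABELS}, got {labels}")
        prev_end: Optional[KabatPosition] = None
        for label, start, end in self.boundaries:
            if end < start:
                raise ValueError(f"{label}: end {end} precedes start {start}")
            if prev_end is not None and not prev_end < start:
                raise ValueError(f"{label} overlaps the preceding region")
            prev_end = end

    def region_of(self, pos: KabatPosition) -> str:
        """Label of the region containing ``pos``; OutOfRangeError if uncovered."""
        for label, start, end in self.boundaries:
            if start <= pos <= end:
                return label
        raise OutOfRangeError(
            f"Kabat position {pos} outside {self.chain_class} region map coverage"
        )

    def is_cdr(self, pos: KabatPosition) -> bool:
        return self.region_of(pos).startswith("CDR")

    @property
    def start(self) -> KabatPosition:
        return self.boundaries[0][1]

    @property
    def end(self) -> KabatPosition:
        return self.boundaries[-1][2]


def _p(number: int, insertion: Optional[str] = None) -> KabatPosition:
    return KabatPosition(number, insertion)


# Kabat CDR definitions: L24-34, L50-56, L89-97; H31-35B, H50-65, H95-102.
KABAT_LIGHT_REGIONS = RegionMap(
    chain_class="kappa",
    boundaries=(
        ("FR1", _p(1), _p(23)),
        ("CDR1", _p(24), _p(34)),
        ("FR2", _p(35), _p(49)),
        ("CDR2", _p(50), _p(56)),
        ("FR3", _p(57), _p(88)),
        ("CDR3", _p(89), _p(97)),
        ("FR4", _p(98), _p(107)),
    ),
)

KABAT_HEAVY_REGIONS = RegionMap(
    chain_class="heavy",
    boundaries=(
        ("FR1", _p(1), _p(30)),
        ("CDR1", _p(31), _p(35, "B")),
        ("FR2", _p(36), _p(49)),
        ("CDR2", _p(50), _p(65)),
        ("FR3", _p(66), _p(94)),
        ("CDR3", _p(95), _p(102)),
        ("FR4", _p(103), _p(113)),
    ),
)


def default_region_map(chain_class: ChainClass) -> RegionMap:
    if chain_class == "heavy":
        return KABAT_HEAVY_REGIONS
    if chain_class in ("kappa", "lambda"):
        return RegionMap(chain_class=chain_class, boundaries=KABAT_LIGHT_REGIONS.boundaries)
    raise ValueError(f"unknown chain class {chain_class!r}")


def region_of(pos: KabatPosition, region_map: RegionMap) -> str:
    """Functional alias for :meth:`RegionMap.region_of`."""
    return region_map.region_of(pos)


def chain_prefix(chain_class: ChainClass) -> str:
    """Single-letter chain prefix used in outputs: H for heavy, L otherwise."""
    return "H" if chain_class == "heavy" else "L"
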