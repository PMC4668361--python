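"""Mining natural framework diversity and emitting a filtered variant library.

The design procedure tallies amino-acid changes from germline across a
numbered repertoire, then retains single-point variants that (i) fall in a
framework region, (ii) are buried (relative solvent accessibility at or
below a cutoff), (iii) are not on the paratope exclusion list, and (iv) are
supported by a minimum number of repertoire sequences.  Each retained
variant becomes one library member named ``<from><position><to>`` (M4L,
E6Q, V48I, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .errors import IncompatibleChainError, LibraryParseError, MissingAnnotationError
from .kabat import KabatPosition, RegionMap
from .numbering import GermlineReference, NumberedSequence, detect_deviations

Chain = Literal["heavy", "light"]


def _chain_of(chain_class: str) -> Chain:
    return "heavy" if chain_class == "heavy" else "light"


@dataclass(frozen=True)
class VariantObservation:
    """A germline deviation observed in the repertoire, with its support count."""

    chain: Chain
    pos: KabatPosition
    from_aa: str
    to_aa: str
    count: int

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError("from_aa and to_aa must differ")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class BurialAnnotation:
    """Relative solvent accessibility of a position (0 = fully buried)."""

    chain: Chain
    pos: KabatPosition
    rsa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rsa <= 1.0:
            raise ValueError(f"rsa must be in [0,1], got {self.rsa}")


@dataclass(frozen=True)
class DesignConfig:
    """Filters applied to observed deviations.

    rsa_max
        Maximum relative solvent accessibility for a position to count as
        buried (default 0.2, the common buried/exposed convention).
    min_count
        Minimum repertoire support; 1 admits any observed natural change.
    excluded_positions
        Paratope or otherwise binding-critical positions to drop.
    framework_only
        Restrict to FR regions (drop CDR observations).
    strict_burial
        If True, an observed position missing from the burial table is an
        error; otherwise missing burial counts as exposed (excluded).
    """

    rsa_max: float = 0.2
    min_count: int = 1
    excluded_positions: frozenset[KabatPosition] = frozenset()
    framework_only: bool = True
    strict_burial: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.rsa_max < 1.0:
            raise ValueError("rsa_max must be in (0,1)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass(frozen=True)
class LibraryVariant:
    """A single-point framework variant retained by the design filters."""

    chain: Chain
    pos: KabatPosition
    from_aa: str
    to_aa: str
    support: int
    filter_log: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return f"{self.from_aa}{self.pos}{self.to_aa}"


def tally_natural_diversity(
    repertoire: Sequence[NumberedSequence], germline: GermlineReference
) -> list[VariantObservation]:
    """Count unique (position, from, to) deviations from germline in a repertoire."""
    chain = _chain_of(germline.chain_class)
    counts: dict[tuple[KabatPosition, str, str], int] = {}
    for seq in repertoire:
        if seq.chain_class != germline.chain_class:
            raise IncompatibleChainError(
                f"{seq.source_id} is {seq.chain_class}, germline is {germline.chain_class}"
            )
        for dev in detect_deviations(seq, germline):
            key = (dev.pos, dev.germline_aa, dev.observed_aa)
            counts[key] = counts.get(key, 0) + 1
    observations = [
        VariantObservation(chain=chain, pos=pos, from_aa=f, to_aa=t, count=c)
        for (pos, f, t), c in counts.items()
    ]
    observations.sort(key=lambda o: (o.pos.sort_key, o.to_aa))
    return observations


def audit_design(
    observations: Sequence[VariantObservation],
    burial: Sequence[BurialAnnotation],
    region_map: RegionMap,
    config: DesignConfig,
) -> pd.DataFrame:
    """Per-observation truth table of every design filter decision."""
    rsa_by_pos = {(b.chain, b.pos): b.rsa for b in burial}
    rows = []
    for obs in observations:
        region = region_map.region_of(obs.pos)
        in_framework = region.startswith("FR")
        rsa = rsa_by_pos.get((obs.chain, obs.pos))
        if rsa is None and config.strict_burial:
            raise MissingAnnotationError(
                f"no burial annotation for {obs.chain} position {obs.pos}"
            )
        buried = rsa is not None and rsa <= config.rsa_max
        not_excluded = obs.pos not in config.excluded_positions
        supported = obs.count >= config.min_count
        retained = (in_framework or not config.framework_only) and buried and not_excluded and supported
        rows.append(
            {
                "chain": obs.chain,
                "pos": str(obs.pos),
                "from_aa": obs.from_aa,
                "to_aa": obs.to_aa,
                "count": obs.count,
                "region": region,
                "rsa": rsa,
                "framework": in_framework,
                "buried": buried,
                "not_excluded": not_excluded,
                "supported": supported,
                "retained": retained,
            }
        )
    return pd.DataFrame(rows)


def design_library(
    observations: Sequence[VariantObservation],
    burial: Sequence[BurialAnnotation],
    region_map: RegionMap,
    config: DesignConfig = DesignConfig(),
) -> list[LibraryVariant]:
    """Retain observed deviations passing all design filters.

    Every retained variant is traceable to an observation; nothing is
    synthesized.  Output is sorted by (chain, position, substituted residue).
    """
    rsa_by_pos = {(b.chain, b.pos): b.rsa for b in burial}
    variants: list[LibraryVariant] = []
    for obs in observations:
        log: list[str] = []
        region = region_map.region_of(obs.pos)
        if config.framework_only:
            if not region.startswith("FR"):
                continue  # non-framework
            log.append("framework")
        rsa = rsa_by_pos.get((obs.chain, obs.pos))
        if rsa is None:
            if config.strict_burial:
                raise MissingAnnotationError(
                    f"no burial annotation for {obs.chain} position {obs.pos}"
                )
            continue  # missing-as-exclude
        if rsa > config.rsa_max:
            continue  # surface-exposed
        log.append("buried")
        if obs.pos in config.excluded_positions:
            continue  # paratope exclusion
        log.append("not-excluded")
        if obs.count < config.min_count:
            continue  # insufficient support
        log.append("supported")
        variants.append(
            LibraryVariant(
                chain=obs.chain,
                pos=obs.pos,
                from_aa=obs.from_aa,
                to_aa=obs.to_aa,
                support=obs.count,
                filter_log=tuple(log),
            )
        )
    variants.sort(key=lambda v: (v.chain, v.pos.sort_key, v.to_aa))
    return variants


# ---------------------------------------------------------------------------
# Library file round trip

_LIBRARY_COLUMNS = [
    "chain",
    "kabat_position",
    "from_aa",
    "to_aa",
    "support",
    "name",
    "filters_passed",
]


def write_library(variants: Sequence[LibraryVariant], path: str | Path) -> None:
    """Write a library TSV; byte-identical for identical inputs."""
    rows = [
        {
            "chain": v.chain,
            "kabat_position": str(v.pos),
            "from_aa": v.from_aa,
            "to_aa": v.to_aa,
            "support": v.support,
            "name": v.name,
            "filters_passed": ",".join(v.filter_log),
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_LIBRARY_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_library(path: str | Path) -> list[LibraryVariant]:
    df = pd.read_csv(
        path, sep="\t", dtype={"kabat_position": str, "filters_passed": str},
        keep_default_na=False,
    )
    missing = set(_LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise LibraryParseError(f"library file missing columns: {sorted(missing)}")
    variants = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            pos = KabatPosition.parse(row.kabat_position)
            variant = LibraryVariant(
                chain=row.chain,
                pos=pos,
                from_aa=row.from_aa,
                to_aa=row.to_aa,
                support=int(row.support),
                filter_log=tuple(f for f in row.filters_passed.split(",") if f),
            )
            if variant.name != row.name:
                raise ValueError(
                    f"stored name {row.name!r} inconsistent with fields ({variant.name})"
                )
        except (ValueError, TypeError) as exc:
            raise LibraryParseError(f"{path}, line {i}: {exc}") from exc
        variants.append(variant)
    return variants
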