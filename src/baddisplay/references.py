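"""Synthetic subgroup germline references.

These are synthetic consensus frameworks in the style of humanized kappa and
VH germlines, built so that the landmark framework positions discussed
throughout the package exist with the expected wild-type residues
(light M4, heavy E6, F27, M34, V37, V48).  They are fixtures for numbering
and library design, not database-derived alleles.
"""

from __future__ import annotations

from .kabat import KabatPosition, default_region_map
from .numbering import GermlineReference

# Synthetic kappa consensus, Kabat 1-107 with Kabat CDR-L boundaries
# (FR1 1-23 | CDR1 24-34 | FR2 35-49 | CDR2 50-56 | FR3 57-88 | CDR3 89-97 | FR4 98-107).
SYNTHETIC_KAPPA_SEQUENCE = (
    "DIQMTQSPSSLSASVGDRVTITC"  # FR1
    "RASQSISSYLN"  # CDR-L1
    "WYQQKPGKAPKLLIY"  # FR2
    "AASSLQS"  # CDR-L2
    "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"  # FR3
    "QQSYSTPLT"  # CDR-L3
    "FGQGTKVEIK"  # FR4
)

# Synthetic VH consensus, Kabat 1-113 (no insertion positions occupied)
# (FR1 1-30 | CDR-H1 31-35 | FR2 36-49 | CDR-H2 50-65 | FR3 66-94 | CDR-H3 95-102 | FR4 103-113).
SYNTHETIC_HEAVY_SEQUENCE = (
    "EVQLVESGGGLVQPGGSLRLSCAASGFTFS"  # FR1
    "SYWMH"  # CDR-H1
    "WVRQAPGKGLEWVA"  # FR2
    "VISYDGSNKYYADSVK"  # CDR-H2
    "GRFTISRDNSKNTLYLQMNSLRAEDTAVY"  # FR3
    "DRGGAVSY"  # CDR-H3
    "WGQGTLVTVSS"  # FR4
)


def _sequential_reference(
    id: str, chain_class: str, subgroup: str, sequence: str
) -> GermlineReference:
    residues = tuple(
        (KabatPosition(i + 1), aa) for i, aa in enumerate(sequence)
    )
    return GermlineReference(
        id=id, chain_class=chain_class, subgroup=subgroup, residues=residues
    )


def synthetic_kappa_germline(subgroup: str = "kappa1") -> GermlineReference:
    """Synthetic kappa light-chain germline (Kabat 1-107)."""
    return _sequential_reference(
        "synthetic-kappa", "kappa", subgroup, SYNTHETIC_KAPPA_SEQUENCE
    )


def synthetic_heavy_germline(subgroup: str = "VH3") -> GermlineReference:
    """Synthetic heavy-chain germline (Kabat 1-113)."""
    return _sequential_reference(
        "synthetic-vh", "heavy", subgroup, SYNTHETIC_HEAVY_SEQUENCE
    )


def synthetic_germline(chain_class: str) -> GermlineReference:
    if chain_class == "heavy":
        return synthetic_heavy_germline()
    if chain_class in ("kappa", "lambda", "light"):
        return synthetic_kappa_germline()
    raise ValueError(f"unknown chain class {chain_class!r}")


def region_map_for(reference: GermlineReference):
    return default_region_map(reference.chain_class)
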