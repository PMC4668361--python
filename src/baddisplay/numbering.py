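"""Kabat numbering by global alignment to a pre-numbered germline reference.

A query variable-domain sequence is aligned globally (affine gaps, BLOSUM62)
against a subgroup germline whose residues already carry Kabat coordinates.
Query residues matched to reference residues inherit the reference position;
query residues aligned against reference gaps receive insertion codes
(A, B, ...) appended to the last assigned number.  Deviations from germline
are then read off position-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import IncompatibleChainError, InvalidAlphabetError, UnalignableSequenceError
from .kabat import AMINO_ACIDS, ChainClass, KabatPosition, RegionMap

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class GermlineReference:
    """A pre-numbered subgroup germline used as numbering and deviation baseline."""

    id: str
    chain_class: ChainClass
    subgroup: str
    residues: tuple[tuple[KabatPosition, str], ...]

    def __post_init__(self) -> None:
        positions = [pos for pos, _ in self.residues]
        if any(not a < b for a, b in zip(positions, positions[1:])):
            raise ValueError("reference Kabat positions must be strictly increasing")
        bad = {aa for _, aa in self.residues if aa not in AMINO_ACIDS}
        if bad:
            raise ValueError(f"reference contains non-amino-acid letters: {sorted(bad)}")

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    @property
    def positions(self) -> tuple[KabatPosition, ...]:
        return tuple(pos for pos, _ in self.residues)

    def residue_at(self, pos: KabatPosition) -> Optional[str]:
        for p, aa in self.residues:
            if p == pos:
                return aa
        return None


@dataclass(frozen=True)
class NumberedSequence:
    """A query sequence with per-residue Kabat coordinates."""

    source_id: str
    chain_class: ChainClass
    residues: tuple[tuple[KabatPosition, str], ...]
    alignment_score: float = 0.0

    def __post_init__(self) -> None:
        positions = [pos for pos, _ in self.residues]
        if any(not a < b for a, b in zip(positions, positions[1:])):
            raise ValueError("numbered positions must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    def as_dict(self) -> dict[KabatPosition, str]:
        return dict(self.residues)


@dataclass(frozen=True)
class Deviation:
    """A single amino-acid difference from germline at a Kabat position."""

    pos: KabatPosition
    germline_aa: str
    observed_aa: str


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython affine convention: a gap of length L scores open + (L-1)*extend.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate_alphabet(sequence: str, allow_x: bool = True) -> None:
    allowed = set(AMINO_ACIDS) | ({"X"} if allow_x else set())
    bad = sorted(set(sequence) - allowed)
    if bad:
        raise InvalidAlphabetError(f"non-amino-acid characters in sequence: {bad}")


def assign_numbering(
    sequence: str,
    reference: GermlineReference,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    min_score: Optional[float] = None,
    source_id: str = "query",
    length_bounds: tuple[int, int] = (60, 150),
) -> NumberedSequence:
    """Assign Kabat numbers to ``sequence`` by global alignment to ``reference``.

    Parameters
    ----------
    sequence
        Amino-acid string, 60-150 residues (variable-domain scale).
    reference
        Pre-numbered subgroup germline.
    gap_open, gap_extend
        Affine gap penalties (positive numbers; applied as negative scores on
        BLOSUM62).  A gap of length L costs ``gap_open + (L-1)*gap_extend``.
    min_score
        Optional floor on the alignment score; below it the sequence is
        rejected as unalignable.

    Insertions relative to the reference receive letter codes appended to the
    preceding assigned number (e.g., residues between 100 and 101 become
    100A, 100B, ...).  Insertions outside CDR interiors are legal but trigger
    a warning, since framework indels are not expected in this coordinate
    system.  Alignment ties resolve deterministically to the aligner's first
    reported path.
    """
    sequence = sequence.strip().upper()
    lo, hi = length_bounds
    if not lo <= len(sequence) <= hi:
        raise ValueError(
            f"sequence length {len(sequence)} outside the {lo}-{hi} domain range"
        )
    if not reference.residues:
        raise ValueError("empty reference")
    _validate_alphabet(sequence)

    aligner = _make_aligner(gap_open, gap_extend)
    alignments = aligner.align(reference.sequence, sequence)
    alignment = alignments[0]
    score = float(alignment.score)
    if min_score is not None and score < min_score:
        raise UnalignableSequenceError(
            f"alignment score {score:.1f} below floor {min_score:.1f} for {source_id}"
        )

    ref_positions = reference.positions
    numbered: list[tuple[KabatPosition, str]] = []
    last_number: Optional[int] = None
    insertion_rank = 0
    ref_idx_row, query_idx_row = alignment.indices
    from .kabat import default_region_map

    region_map = default_region_map(reference.chain_class)
    for ref_i, query_i in zip(ref_idx_row, query_idx_row):
        if query_i < 0:
            # deletion in the query: reference position is skipped
            if ref_i >= 0:
                last_number = ref_positions[ref_i].number
                insertion_rank = 0
            continue
        aa = sequence[query_i]
        if ref_i >= 0:
            pos = ref_positions[ref_i]
            last_number = pos.number
            insertion_rank = 0
        else:
            if last_number is None:
                raise UnalignableSequenceError(
                    f"{source_id}: query residues precede the first reference position; "
                    "cannot assign an insertion code before Kabat 1"
                )
            insertion_rank += 1
            if insertion_rank > 26:
                raise UnalignableSequenceError(
                    f"{source_id}: more than 26 consecutive insertions after {last_number}"
                )
            pos = KabatPosition(last_number, chr(ord("A") + insertion_rank - 1))
            try:
                if not region_map.is_cdr(KabatPosition(last_number)):
                    warnings.warn(
                        f"{source_id}: insertion {pos} outside a CDR interior",
                        stacklevel=2,
                    )
            except Exception:
                pass
        numbered.append((pos, aa))

    return NumberedSequence(
        source_id=source_id,
        chain_class=reference.chain_class,
        residues=tuple(numbered),
        alignment_score=score,
    )


def detect_deviations(
    seq: NumberedSequence, germline: GermlineReference
) -> list[Deviation]:
    """Position-wise differences from germline over the shared Kabat positions."""
    if seq.chain_class != germline.chain_class:
        raise IncompatibleChainError(
            f"sequence is {seq.chain_class}, germline is {germline.chain_class}"
        )
    observed = seq.as_dict()
    out = [
        Deviation(pos, germ_aa, observed[pos])
        for pos, germ_aa in germline.residues
        if pos in observed and observed[pos] != germ_aa
    ]
    out.sort(key=lambda d: d.pos.sort_key)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from an amino-acid FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_reference_tsv(
    path: str | Path, id: str, chain_class: ChainClass, subgroup: str = ""
) -> GermlineReference:
    """Load a reference from TSV columns: kabat_number, insertion, aa[, region]."""
    df = pd.read_csv(path, sep="\t", dtype={"insertion": str}, keep_default_na=False)
    residues = tuple(
        (KabatPosition(int(row.kabat_number), row.insertion or None), row.aa)
        for row in df.itertuples()
    )
    return GermlineReference(id=id, chain_class=chain_class, subgroup=subgroup, residues=residues)


def write_reference_tsv(reference: GermlineReference, region_map: RegionMap, path: str | Path) -> None:
    rows = [
        {
            "kabat_number": pos.number,
            "insertion": pos.insertion or "",
            "aa": aa,
            "region": region_map.region_of(pos),
        }
        for pos, aa in reference.residues
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_numbered_tsv(
    sequences: Iterable[NumberedSequence], region_map: RegionMap, path: str | Path
) -> None:
    """Serialize numbered sequences: source_id, kabat_position, aa, region."""
    rows = []
    for seq in sequences:
        for pos, aa in seq.residues:
            rows.append(
                {
                    "source_id": seq.source_id,
                    "kabat_position": str(pos),
                    "aa": aa,
                    "region": region_map.region_of(pos),
                }
            )
    pd.DataFrame(rows, columns=["source_id", "kabat_position", "aa", "region"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_numbered_tsv(path: str | Path, chain_class: ChainClass) -> list[NumberedSequence]:
    df = pd.read_csv(path, sep="\t", dtype={"kabat_position": str})
    out = []
    for source_id, group in df.groupby("source_id", sort=False):
        residues = tuple(
            (KabatPosition.parse(row.kabat_position), row.aa) for row in group.itertuples()
        )
        out.append(
            NumberedSequence(
                source_id=str(source_id), chain_class=chain_class, residues=residues
            )
        )
    return out
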