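"""Synthetic repertoire generator emulating somatic hypermutation (SHM).

Generates subgroup-matched variable-domain sequences as germline copies with
independent per-position amino-acid substitutions, plus optional "planted"
variants carried at controlled frequencies.  The generator keeps an exact
ground-truth mutation table so the numbering and library-design stages can
be validated end to end without any external repertoire database.

SHM is modeled at the amino-acid level: each position mutates independently
with a small per-position probability (hotspot structure can be expressed
through relative position weights), and substitutions default to uniform
over the 19 alternative residues.  Indels are off by default; an optional
insertion rate exists solely to exercise insertion-code numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .kabat import AMINO_ACIDS, KabatPosition
from .numbering import GermlineReference


@dataclass(frozen=True)
class PlantedVariant:
    """A substitution to carry at a target population frequency."""

    pos: KabatPosition
    to_aa: str
    target_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_frequency <= 1.0:
            raise ValueError("target_frequency must be in [0,1]")
        if self.to_aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid {self.to_aa!r}")


@dataclass(frozen=True)
class SHMConfig:
    """Parameters of the synthetic SHM repertoire.

    n_sequences
        Repertoire size.
    per_position_rate
        Baseline probability that any one position carries a substitution.
    position_weights
        Optional relative weights (mean-normalized); a weight of 2 doubles
        that position's substitution probability.
    substitution_model
        'uniform' (19 equiprobable alternatives) or a {from: {to: prob}}
        transition-biased table.
    planted_variants
        Substitutions carried at Binomial(n, target_frequency) counts,
        applied after (and overriding) background SHM.
    insertion_rate
        Probability that a sequence carries one extra residue inserted in
        the CDR3 interior (default 0; exists to exercise insertion codes).
    seed
        RNG seed; fixed seed gives a byte-identical repertoire.
    """

    n_sequences: int
    per_position_rate: float = 0.01
    position_weights: Optional[dict[KabatPosition, float]] = None
    substitution_model: str | dict = "uniform"
    planted_variants: tuple[PlantedVariant, ...] = ()
    insertion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_position_rate <= 1.0:
            raise ConfigError("per_position_rate must be in [0,1]")
        if self.position_weights and any(w < 0 for w in self.position_weights.values()):
            raise ConfigError("position weights must be >= 0")
        seen = set()
        for pv in self.planted_variants:
            key = (pv.pos, pv.to_aa)
            if key in seen:
                raise ConfigError(f"duplicate planted variant at {pv.pos}->{pv.to_aa}")
            seen.add(key)
        by_pos: dict[KabatPosition, float] = {}
        for pv in self.planted_variants:
            by_pos[pv.pos] = by_pos.get(pv.pos, 0.0) + pv.target_frequency
        for pos, total in by_pos.items():
            if total > 1.0 + 1e-12:
                raise ConfigError(
                    f"planted frequencies at {pos} sum to {total:.3f} > 1"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SHMConfig":
        raw = yaml.safe_load(Path(path).read_text())
        planted = tuple(
            PlantedVariant(
                pos=KabatPosition.parse(str(p["pos"])),
                to_aa=p["to_aa"],
                target_frequency=float(p["target_frequency"]),
            )
            for p in raw.pop("planted_variants", [])
        )
        weights = raw.pop("position_weights", None)
        if weights:
            weights = {KabatPosition.parse(str(k)): float(v) for k, v in weights.items()}
        return cls(planted_variants=planted, position_weights=weights, **raw)


@dataclass(frozen=True)
class TruthRecord:
    sequence_id: str
    pos: KabatPosition
    from_aa: str
    to_aa: str


@dataclass(frozen=True)
class SyntheticRepertoire:
    """Generated sequences plus their exact deviation table from germline."""

    germline: GermlineReference
    sequences: tuple[tuple[str, str], ...]  # (id, amino-acid string)
    truth: tuple[TruthRecord, ...]

    def truth_counts(self) -> dict[tuple[KabatPosition, str, str], int]:
        """Support count per unique (pos, from, to) substitution."""
        counts: dict[tuple[KabatPosition, str, str], int] = {}
        for rec in self.truth:
            key = (rec.pos, rec.from_aa, rec.to_aa)
            counts[key] = counts.get(key, 0) + 1
        return counts


def _substitute(rng: np.random.Generator, from_aa: str, model: str | dict) -> str:
    if model == "uniform":
        alternatives = [aa for aa in AMINO_ACIDS if aa != from_aa]
        return alternatives[rng.integers(len(alternatives))]
    table = model.get(from_aa)
    if not table:
        alternatives = [aa for aa in AMINO_ACIDS if aa != from_aa]
        return alternatives[rng.integers(len(alternatives))]
    targets, probs = zip(*sorted(table.items()))
    probs = np.asarray(probs, dtype=float)
    return targets[rng.choice(len(targets), p=probs / probs.sum())]


def simulate_repertoire(
    germline: GermlineReference, config: SHMConfig
) -> SyntheticRepertoire:
    """Generate a seeded synthetic SHM repertoire with an exact truth table."""
    rng = np.random.default_rng(config.seed)
    positions = germline.positions
    germ_aa = dict(germline.residues)
    n_pos = len(positions)

    if config.position_weights:
        w = np.array([config.position_weights.get(p, 1.0) for p in positions])
        rates = np.minimum(config.per_position_rate * w / w.mean(), 1.0)
    else:
        rates = np.full(n_pos, config.per_position_rate)

    # planted carriers drawn exclusively per position (frequencies sum <= 1)
    planted_by_pos: dict[KabatPosition, list[PlantedVariant]] = {}
    for pv in config.planted_variants:
        planted_by_pos.setdefault(pv.pos, []).append(pv)
    planted_choice: dict[KabatPosition, np.ndarray] = {}
    for pos, pvs in planted_by_pos.items():
        probs = [pv.target_frequency for pv in pvs]
        probs.append(1.0 - sum(probs))
        planted_choice[pos] = rng.choice(
            len(pvs) + 1, size=config.n_sequences, p=np.asarray(probs)
        )

    cdr3_interior = [p for p in positions if 90 <= p.number <= 96]

    sequences: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    width = len(str(max(config.n_sequences - 1, 1)))
    for i in range(config.n_sequences):
        seq_id = f"seq{i:0{width}d}"
        residues = {pos: germ_aa[pos] for pos in positions}
        hit = rng.random(n_pos) < rates
        for j in np.flatnonzero(hit):
            pos = positions[j]
            residues[pos] = _substitute(rng, germ_aa[pos], config.substitution_model)
        for pos, pvs in planted_by_pos.items():
            k = planted_choice[pos][i]
            if k < len(pvs):
                residues[pos] = pvs[k].to_aa
            else:
                residues[pos] = germ_aa[pos]  # non-carriers revert background hits
        for pos in positions:
            if residues[pos] != germ_aa[pos]:
                truth.append(TruthRecord(seq_id, pos, germ_aa[pos], residues[pos]))
        letters = [residues[pos] for pos in positions]
        if config.insertion_rate and rng.random() < config.insertion_rate and cdr3_interior:
            at = positions.index(cdr3_interior[rng.integers(len(cdr3_interior))])
            letters.insert(at + 1, AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
        sequences.append((seq_id, "".join(letters)))

    return SyntheticRepertoire(
        germline=germline, sequences=tuple(sequences), truth=tuple(truth)
    )


def write_repertoire(
    repertoire: SyntheticRepertoire, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write FASTA plus truth TSV; returns the two paths."""
    out_prefix = Path(out_prefix)
    fasta = out_prefix.with_suffix(".fasta")
    truth = out_prefix.with_suffix(".truth.tsv")
    with open(fasta, "w") as fh:
        for seq_id, seq in repertoire.sequences:
            fh.write(f">{seq_id}\n{seq}\n")
    import pandas as pd

    pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "kabat_position": str(r.pos),
                "from_aa": r.from_aa,
                "to_aa": r.to_aa,
            }
            for r in repertoire.truth
        ],
        columns=["sequence_id", "kabat_position", "from_aa", "to_aa"],
    ).to_csv(truth, sep="\t", index=False, lineterminator="\n")
    return fasta, truth
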