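"""Quantification of selection outcomes.

Three readouts are supported:

* dual-marker plating — the ratio of marker-bearing (e.g., tetracycline
  resistant) to non-marker colonies estimates the spiked clone's abundance;
  fold enrichment across a sort is the ratio of output to input ratios,
  with Poisson error propagation on the log scale;
* sequenced clone counts — per-round clone frequencies with Wilson 95%
  confidence intervals;
* enrichment calls — enriched / depleted / neutral / not_detected per clone
  between a first and last round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    DegenerateRatioError,
    EmptyPlateError,
    InsufficientRoundsError,
    UndefinedEnrichmentError,
)

Z95 = 1.959963984540054


@dataclass(frozen=True)
class PlateCount:
    """Colony counts from one sample plated on permissive and restrictive media."""

    sample_id: str
    colonies_total: int
    colonies_marker: int
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.colonies_marker > self.colonies_total:
            raise ValueError("marker colonies cannot exceed total colonies")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")


@dataclass(frozen=True)
class RatioEstimate:
    """Marker:non-marker abundance ratio with log-scale standard error."""

    ratio: float
    se_log: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be >= 0")


@dataclass(frozen=True)
class FoldEnrichment:
    """Output/input ratio-of-ratios with a log-normal 95% interval."""

    fold: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CloneCounts:
    """Sequenced-clone tallies for one selection round."""

    round_index: int
    counts: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def ratio_from_plates(pc: PlateCount) -> RatioEstimate:
    """Marker ratio = marker / (total - marker); SE by Poisson propagation.

    Both plates are assumed to sample the same dilution of the same culture,
    so the dilution factor cancels in the ratio.  ``se_log`` is
    sqrt(1/marker + 1/(total-marker)), the delta-method error of the log
    ratio of two Poisson counts; it is reported as inf when the marker
    count is zero.
    """
    if pc.colonies_total == 0:
        raise EmptyPlateError(f"{pc.sample_id}: zero total colonies")
    non_marker = pc.colonies_total - pc.colonies_marker
    if non_marker == 0:
        raise DegenerateRatioError(
            f"{pc.sample_id}: marker colonies equal total colonies; ratio undefined"
        )
    ratio = pc.colonies_marker / non_marker
    se_log = (
        math.sqrt(1 / pc.colonies_marker + 1 / non_marker)
        if pc.colonies_marker > 0
        else math.inf
    )
    return RatioEstimate(ratio=ratio, se_log=se_log)


def fold_enrichment(r_in: RatioEstimate, r_out: RatioEstimate) -> FoldEnrichment:
    """Fold enrichment across a sort: output ratio / input ratio."""
    if r_in.ratio <= 0:
        raise UndefinedEnrichmentError("input ratio is zero; enrichment undefined")
    fold = r_out.ratio / r_in.ratio
    se = math.sqrt(r_in.se_log**2 + r_out.se_log**2)
    if fold > 0 and math.isfinite(se):
        log_fold = math.log(fold)
        ci = (math.exp(log_fold - Z95 * se), math.exp(log_fold + Z95 * se))
    else:
        ci = (0.0, math.inf)
    return FoldEnrichment(fold=fold, ci_low=ci[0], ci_high=ci[1])


def wilson_interval(count: int, n_total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    low, high = proportion_confint(count, n_total, alpha=alpha, method="wilson")
    return float(low), float(high)


def clone_frequencies(
    cc: CloneCounts, alpha: float = 0.05
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Per-clone frequency with Wilson interval; frequencies sum to 1."""
    if cc.n_total < 1:
        raise ValueError("n_total must be >= 1")
    return {
        clone: (count / cc.n_total, wilson_interval(count, cc.n_total, alpha))
        for clone, count in cc.counts.items()
    }


def call_enrichment(
    rounds: Sequence[CloneCounts], min_fold: float = 2.0, alpha: float = 0.05
) -> dict[str, str]:
    """Classify each clone between the first and last round.

    not_detected: final count zero.  enriched / depleted: frequency changed
    by at least ``min_fold`` with non-overlapping Wilson intervals.
    Otherwise neutral.
    """
    if len(rounds) < 2:
        raise InsufficientRoundsError("need at least two rounds for enrichment calls")
    first, last = rounds[0], rounds[-1]
    clones = sorted(set(first.counts) | set(last.counts))
    calls: dict[str, str] = {}
    for clone in clones:
        c0, c1 = first.counts.get(clone, 0), last.counts.get(clone, 0)
        if c1 == 0:
            calls[clone] = "not_detected"
            continue
        f0, f1 = c0 / first.n_total, c1 / last.n_total
        lo0, hi0 = wilson_interval(c0, first.n_total, alpha)
        lo1, hi1 = wilson_interval(c1, last.n_total, alpha)
        disjoint = lo1 > hi0 or hi1 < lo0
        if f0 == 0:
            calls[clone] = "enriched" if disjoint else "neutral"
        elif f1 >= min_fold * f0 and disjoint:
            calls[clone] = "enriched"
        elif f1 <= f0 / min_fold and disjoint:
            calls[clone] = "depleted"
        else:
            calls[clone] = "neutral"
    return calls


def enrichment_report(
    rounds: Sequence[CloneCounts], min_fold: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Long-format report: clone, round, count, frequency, Wilson bounds, call."""
    calls = call_enrichment(rounds, min_fold=min_fold, alpha=alpha)
    rows = []
    for cc in rounds:
        freqs = clone_frequencies(cc, alpha)
        for clone in sorted(set(cc.counts) | set(calls)):
            count = cc.counts.get(clone, 0)
            freq, (lo, hi) = freqs.get(
                clone, (0.0, wilson_interval(0, cc.n_total, alpha))
            )
            rows.append(
                {
                    "clone_id": clone,
                    "round": cc.round_index,
                    "count": count,
                    "frequency": freq,
                    "ci_low": lo,
                    "ci_high": hi,
                    "call": calls[clone],
                }
            )
    return pd.DataFrame(rows)


def read_clone_counts(path) -> list[CloneCounts]:
    """Read per-round clone counts from TSV (clone_id, round, count)."""
    df = pd.read_csv(path, sep="\t")
    rounds = []
    for r, group in df.groupby("round", sort=True):
        counts = {
            str(cid): int(c) for cid, c in zip(group["clone_id"], group["count"])
        }
        rounds.append(CloneCounts(round_index=int(r), counts=counts))
    return rounds


def read_plate_counts(path) -> list[PlateCount]:
    """Read plate counts from TSV (sample_id, colonies_total, colonies_marker[, dilution_factor])."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        out.append(
            PlateCount(
                sample_id=str(row.sample_id),
                colonies_total=int(row.colonies_total),
                colonies_marker=int(row.colonies_marker),
                dilution_factor=float(getattr(row, "dilution_factor", 1.0)),
            )
        )
    return out
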