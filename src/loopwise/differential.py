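"""Two-condition loop comparison: filter, normalize, match, call gained/lost.

Loops are first filtered per condition (FDR strictly below ``fdr_max`` and
PET count at least ``min_pets``), normalized to PETs per million valid read
pairs, then matched across conditions by anchor-midpoint bins. A matched
pair present on one side only is a change *in number*; a pair present on
both sides whose normalized ratio clears ``strength_fold`` is a change *in
strength*; everything else is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .connectome import CATEGORIES, ClassifiedLoop
from .io_formats import LoopRecord, LoopSet

GAINED = "gained"
LOST = "lost"
UNCHANGED = "unchanged"

MODE_NUMBER = "number"
MODE_STRENGTH = "strength"
MODE_NONE = "none"

BinKey = Tuple[str, int, int]


@dataclass(frozen=True)
class NormalizedLoop:
    """A loop with its depth-normalized support (PETs per million valid pairs)."""

    loop: LoopRecord
    norm_count: float


def filter_loops(loopset: LoopSet, fdr_max: float = 0.05, min_pets: int = 5) -> LoopSet:
    """Keep loops with ``fdr < fdr_max`` (strict) and ``pet_count >= min_pets``."""
    kept = [lp for lp in loopset.loops if lp.fdr < fdr_max and lp.pet_count >= min_pets]
    out = LoopSet(
        condition=loopset.condition,
        loops=kept,
        total_valid_pairs=loopset.total_valid_pairs,
    )
    out.n_filtered_out = len(loopset.loops) - len(kept)  # type: ignore[attr-defined]
    return out


def normalize(loopset: LoopSet) -> List[NormalizedLoop]:
    """PETs per million valid pairs; the raw count stays on the wrapped record."""
    if loopset.total_valid_pairs <= 0:
        raise ValueError("total_valid_pairs must be > 0")
    scale = 1e6 / loopset.total_valid_pairs
    return [NormalizedLoop(lp, lp.pet_count * scale) for lp in loopset.loops]


def bin_key(loop: LoopRecord, match_bin_bp: int) -> BinKey:
    """(chrom, anchor1-midpoint bin, anchor2-midpoint bin) at the match resolution."""
    return (
        loop.chrom,
        loop.anchor1.midpoint // match_bin_bp,
        loop.anchor2.midpoint // match_bin_bp,
    )


@dataclass
class BinnedSide:
    """All same-condition loops falling in one anchor-bin pair, aggregated.

    Counts are summed; the representative record (highest PET count, ties by
    loop_id) carries the coordinates used for category/distance reporting.
    """

    loops: List[NormalizedLoop]

    @property
    def pet_count(self) -> int:
        return sum(nl.loop.pet_count for nl in self.loops)

    @property
    def norm_count(self) -> float:
        return sum(nl.norm_count for nl in self.loops)

    @property
    def representative(self) -> LoopRecord:
        return max(self.loops, key=lambda nl: (nl.loop.pet_count, nl.loop.loop_id)).loop


@dataclass
class MatchedLoopPair:
    """Cross-condition pairing of loops sharing an anchor-bin key."""

    key: BinKey
    control: Optional[BinnedSide]
    treated: Optional[BinnedSide]

    def __post_init__(self) -> None:
        if self.control is None and self.treated is None:
            raise ValueError("matched pair must have at least one side")


@dataclass
class DifferentialLoop:
    """A matched pair with its gained/lost/unchanged call.

    ``mode`` is *number* when the loop exists on one side only and *strength*
    when both sides exist and the normalized ratio clears the fold threshold.
    ``category``/``distance`` are attached from the side where the loop
    exists (treated for gained, control for lost) by
    :func:`annotate_differential`.
    """

    pair: MatchedLoopPair
    status: str
    mode: str
    log2_ratio: float = math.nan
    category: Optional[str] = None
    distance: Optional[int] = None

    @property
    def key(self) -> BinKey:
        return self.pair.key

    @property
    def existing_side(self) -> BinnedSide:
        """The side that defines this loop: treated if gained, control if lost."""
        if self.status == GAINED:
            assert self.pair.treated is not None
            return self.pair.treated
        if self.status == LOST:
            assert self.pair.control is not None
            return self.pair.control
        assert self.pair.treated is not None
        return self.pair.treated


def match_loops(
    control: Sequence[NormalizedLoop],
    treated: Sequence[NormalizedLoop],
    match_bin_bp: int = 5_000,
) -> List[MatchedLoopPair]:
    """Pair loops across conditions by (chrom, mid1 bin, mid2 bin).

    Every input loop contributes to exactly one pair; same-condition loops
    sharing a key are aggregated by summing counts. Output order is sorted
    by key for determinism.
    """
    by_key: Dict[BinKey, Tuple[List[NormalizedLoop], List[NormalizedLoop]]] = {}
    for nl in control:
        by_key.setdefault(bin_key(nl.loop, match_bin_bp), ([], []))[0].append(nl)
    for nl in treated:
        by_key.setdefault(bin_key(nl.loop, match_bin_bp), ([], []))[1].append(nl)
    pairs = []
    for key in sorted(by_key):
        ctrl, trt = by_key[key]
        pairs.append(
            MatchedLoopPair(
                key=key,
                control=BinnedSide(ctrl) if ctrl else None,
                treated=BinnedSide(trt) if trt else None,
            )
        )
    return pairs


def call_differential(
    pairs: Sequence[MatchedLoopPair],
    strength_fold: float = 1.5,
) -> List[DifferentialLoop]:
    """Call each matched pair gained / lost / unchanged.

    One-sided pairs change *in number*. Two-sided pairs change *in strength*
    when treated/control normalized counts differ by at least
    ``strength_fold`` in either direction (inclusive).
    """
    if strength_fold <= 1.0:
        raise ValueError(f"strength_fold must be > 1, got {strength_fold}")
    out = []
    for pair in pairs:
        if pair.control is None:
            out.append(DifferentialLoop(pair, GAINED, MODE_NUMBER, math.inf))
        elif pair.treated is None:
            out.append(DifferentialLoop(pair, LOST, MODE_NUMBER, -math.inf))
        else:
            c, t = pair.control.norm_count, pair.treated.norm_count
            ratio = math.inf if c == 0 else t / c
            log2_ratio = math.log2(ratio) if ratio > 0 else -math.inf
            if ratio >= strength_fold:
                out.append(DifferentialLoop(pair, GAINED, MODE_STRENGTH, log2_ratio))
            elif ratio <= 1.0 / strength_fold:
                out.append(DifferentialLoop(pair, LOST, MODE_STRENGTH, log2_ratio))
            else:
                out.append(DifferentialLoop(pair, UNCHANGED, MODE_NONE, log2_ratio))
    return out


def annotate_differential(
    diffs: Sequence[DifferentialLoop],
    classified_control: Dict[str, ClassifiedLoop],
    classified_treated: Dict[str, ClassifiedLoop],
) -> None:
    """Attach category and distance from the side where each loop exists.

    Gained loops take both from the treated representative, lost from the
    control representative; unchanged loops use the treated side.
    """
    for d in diffs:
        lookup = classified_control if d.status == LOST else classified_treated
        cl = lookup[d.existing_side.representative.loop_id]
        d.category = cl.category
        d.distance = cl.distance


def _lower_median(values: Sequence[int]) -> Optional[int]:
    if not values:
        return None
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def summarize_differential(
    diffs: Sequence[DifferentialLoop],
    long_range_bp: int = 20_000,
) -> pd.DataFrame:
    """Counts per status x category, with totals, medians and long-range tallies.

    Rows: one per (status, category) with a count, plus a ``total`` row per
    status whose count is the sum over that status's categories; per-row
    lower-median distance and a strict ``> long_range_bp`` count.
    """
    rows = []
    for status in (GAINED, LOST, UNCHANGED):
        sel = [d for d in diffs if d.status == status]
        for cat in CATEGORIES:
            in_cat = [d for d in sel if d.category == cat]
            dists = [d.distance for d in in_cat if d.distance is not None]
            rows.append(
                {
                    "status": status,
                    "category": cat,
                    "count": len(in_cat),
                    "median_distance_bp": _lower_median(dists),
                    "long_range_count": sum(1 for x in dists if x > long_range_bp),
                }
            )
        dists_all = [d.distance for d in sel if d.distance is not None]
        rows.append(
            {
                "status": status,
                "category": "total",
                "count": len(sel),
                "median_distance_bp": _lower_median(dists_all),
                "long_range_count": sum(1 for x in dists_all if x > long_range_bp),
            }
        )
    return pd.DataFrame(rows, columns=["status", "category", "count", "median_distance_bp", "long_range_count"])


def differential_frame(diffs: Sequence[DifferentialLoop]) -> pd.DataFrame:
    """Flat differential-loop table for TSV output, sorted by bin key."""
    rows = []
    for d in sorted(diffs, key=lambda x: x.key):
        rep = d.existing_side.representative
        rows.append(
            {
                "chrom": d.key[0],
                "bin1": d.key[1],
                "bin2": d.key[2],
                "status": d.status,
                "mode": d.mode,
                "control_norm": d.pair.control.norm_count if d.pair.control else 0.0,
                "treated_norm": d.pair.treated.norm_count if d.pair.treated else 0.0,
                "pet_count": d.existing_side.pet_count,
                "rep_loop_id": rep.loop_id,
                "log2_ratio": d.log2_ratio,
                "category": d.category,
                "distance_bp": d.distance,
            }
        )
    columns = [
        "chrom", "bin1", "bin2", "status", "mode", "control_norm", "treated_norm",
        "pet_count", "rep_loop_id", "log2_ratio", "category", "distance_bp",
    ]
    return pd.DataFrame(rows, columns=columns)
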