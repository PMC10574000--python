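"""Anchor annotation and loop classification into EEI / EPI / PPI.

An anchor overlapping any promoter window is a *promoter* (promoter takes
precedence over enhancer when both overlap); otherwise an anchor overlapping
any H3K27ac peak is an *enhancer*; otherwise *other*. Loop categories follow
from the unordered pair of anchor classes; loops touching an *other* anchor
form a fourth category excluded from the EEI/EPI/PPI percentage denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .genome import GenomicInterval, IntervalIndex
from .io_formats import LoopRecord

PROMOTER = "promoter"
ENHANCER = "enhancer"
OTHER = "other"

EEI = "EEI"
EPI = "EPI"
PPI = "PPI"
CATEGORIES = (EEI, EPI, PPI, OTHER)


@dataclass(frozen=True)
class AnchorAnnotation:
    """The regulatory class of one loop anchor plus its supporting feature ids."""

    anchor: GenomicInterval
    cls: str
    evidence: tuple

    def __post_init__(self) -> None:
        if self.cls not in (PROMOTER, ENHANCER, OTHER):
            raise ValueError(f"unknown anchor class {self.cls!r}")


@dataclass(frozen=True)
class ClassifiedLoop:
    """A loop with its EEI/EPI/PPI/other category and midpoint distance (bp)."""

    loop: LoopRecord
    anchor1_class: str
    anchor2_class: str
    category: str
    distance: int


def classify_anchor(
    anchor: GenomicInterval,
    promoter_index: IntervalIndex,
    peak_index: IntervalIndex,
) -> AnchorAnnotation:
    """Assign exactly one class to an anchor; promoter wins over enhancer."""
    promoter_hits = sorted(str(p) for p in promoter_index.query(anchor))
    if promoter_hits:
        return AnchorAnnotation(anchor, PROMOTER, tuple(promoter_hits))
    peak_hits = sorted(str(p) for p in peak_index.query(anchor))
    if peak_hits:
        return AnchorAnnotation(anchor, ENHANCER, tuple(peak_hits))
    return AnchorAnnotation(anchor, OTHER, ())


def _pair_category(cls1: str, cls2: str) -> str:
    pair = frozenset((cls1, cls2))
    if OTHER in pair:
        return OTHER
    if pair == {PROMOTER}:
        return PPI
    if pair == {ENHANCER}:
        return EEI
    return EPI


def loop_distance(loop: LoopRecord) -> int:
    """Anchor-midpoint separation in bp (floor midpoints); 0 for identical anchors."""
    if loop.anchor1.chrom != loop.anchor2.chrom:
        raise ValueError(f"trans loop has no distance: {loop.loop_id}")
    return abs(loop.anchor2.midpoint - loop.anchor1.midpoint)


def classify_loop(
    loop: LoopRecord,
    ann1: AnchorAnnotation,
    ann2: AnchorAnnotation,
) -> ClassifiedLoop:
    """Categorise a loop from its two anchor annotations (order-invariant)."""
    return ClassifiedLoop(
        loop=loop,
        anchor1_class=ann1.cls,
        anchor2_class=ann2.cls,
        category=_pair_category(ann1.cls, ann2.cls),
        distance=loop_distance(loop),
    )


def classify_loops(
    loops: Iterable[LoopRecord],
    promoter_index: IntervalIndex,
    peak_index: IntervalIndex,
) -> List[ClassifiedLoop]:
    """Annotate both anchors of each loop and classify it."""
    out = []
    for loop in loops:
        ann1 = classify_anchor(loop.anchor1, promoter_index, peak_index)
        ann2 = classify_anchor(loop.anchor2, promoter_index, peak_index)
        out.append(classify_loop(loop, ann1, ann2))
    return out


def _lower_median(values: Sequence[int]) -> Optional[int]:
    """Lower median (no interpolation) so distances stay integral bp."""
    if not values:
        return None
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


@dataclass
class ConnectomeSummary:
    """Counts, EEI/EPI/PPI percentages, per-category median distances, long-range share."""

    counts: Dict[str, int]
    percentages: Dict[str, Optional[float]]
    median_distance: Dict[str, Optional[int]]
    long_range_count: int
    long_range_fraction: Optional[float]
    long_range_bp: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            rows.append(
                {
                    "category": cat,
                    "count": self.counts[cat],
                    "percent_of_epi_eei_ppi": self.percentages.get(cat),
                    "median_distance_bp": self.median_distance[cat],
                }
            )
        return pd.DataFrame(rows)


def summarize_connectome(
    classified: Sequence[ClassifiedLoop],
    long_range_bp: int = 20_000,
) -> ConnectomeSummary:
    """Tally categories and distances.

    Percentages use EEI+EPI+PPI as denominator (loops with an unclassifiable
    anchor are outside it) and are None when that denominator is zero.
    Long-range means distance strictly greater than ``long_range_bp``.
    """
    counts = {cat: 0 for cat in CATEGORIES}
    dists: Dict[str, List[int]] = {cat: [] for cat in CATEGORIES}
    n_long = 0
    for cl in classified:
        counts[cl.category] += 1
        dists[cl.category].append(cl.distance)
        if cl.distance > long_range_bp:
            n_long += 1
    denom = counts[EEI] + counts[EPI] + counts[PPI]
    percentages: Dict[str, Optional[float]] = {
        cat: (100.0 * counts[cat] / denom if denom else None) for cat in (EEI, EPI, PPI)
    }
    n_total = len(classified)
    return ConnectomeSummary(
        counts=counts,
        percentages=percentages,
        median_distance={cat: _lower_median(dists[cat]) for cat in CATEGORIES},
        long_range_count=n_long,
        long_range_fraction=(n_long / n_total if n_total else None),
        long_range_bp=long_range_bp,
    )


def classified_frame(classified: Sequence[ClassifiedLoop]) -> pd.DataFrame:
    """Flat table of classified loops for TSV output."""
    rows = [
        {
            "loop_id": cl.loop.loop_id,
            "chrom": cl.loop.chrom,
            "a1_start": cl.loop.anchor1.start,
            "a1_end": cl.loop.anchor1.end,
            "a2_start": cl.loop.anchor2.start,
            "a2_end": cl.loop.anchor2.end,
            "pet_count": cl.loop.pet_count,
            "fdr": cl.loop.fdr,
            "anchor1_class": cl.anchor1_class,
            "anchor2_class": cl.anchor2_class,
            "category": cl.category,
            "distance_bp": cl.distance,
        }
        for cl in classified
    ]
    columns = [
        "loop_id", "chrom", "a1_start", "a1_end", "a2_start", "a2_end",
        "pet_count", "fdr", "anchor1_class", "anchor2_class", "category", "distance_bp",
    ]
    return pd.DataFrame(rows, columns=columns)
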