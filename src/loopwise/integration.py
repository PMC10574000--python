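"""Link differential loops to differentially expressed genes and rank them.

Significantly upregulated genes (log2FC > 1, padj < 0.05) are linked to
*gained* loops and significantly downregulated genes (log2FC <= -1,
padj < 0.05) to *lost* loops whenever a loop anchor overlaps the gene locus
(promoter window united with the gene body) and the loop's PET count on the
side where it exists is at least ``min_link_pets``. Linked genes are ranked
by adjusted p-value, the printed ranking key; ties (e.g. two genes both at
padj = 0) are broken by |log2FC| then gene id so the order is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .differential import GAINED, LOST, BinKey, DifferentialLoop
from .genome import GenomicInterval, IntervalIndex, TSSRecord, build_index, promoter_window
from .io_formats import DEGRecord

UP = "up"
DOWN = "down"

_DIRECTION_FOR_STATUS = {GAINED: UP, LOST: DOWN}


def select_degs(
    table: Sequence[DEGRecord],
    up_log2fc_min: float = 1.0,
    down_log2fc_max: float = -1.0,
    padj_max: float = 0.05,
) -> Tuple[List[DEGRecord], List[DEGRecord]]:
    """Split a DE table into (up, down) significant sets.

    Up requires ``log2fc > up_log2fc_min`` strictly; down requires
    ``log2fc <= down_log2fc_max`` inclusively; both require
    ``padj < padj_max`` strictly — the printed inequality forms.
    """
    up = [d for d in table if d.log2fc > up_log2fc_min and d.padj < padj_max]
    down = [d for d in table if d.log2fc <= down_log2fc_max and d.padj < padj_max]
    return up, down


def gene_locus(tss: TSSRecord, promoter_flank_bp: int = 2000) -> GenomicInterval:
    """Single-interval union of the promoter window and the gene body."""
    prom = promoter_window(tss, promoter_flank_bp)
    return GenomicInterval(
        tss.chrom,
        min(prom.start, tss.gene_body.start),
        max(prom.end, tss.gene_body.end),
    )


def build_locus_index(
    tss_records: Iterable[TSSRecord],
    promoter_flank_bp: int = 2000,
) -> IntervalIndex:
    """Overlap index of gene loci keyed by gene_id."""
    return build_index(
        (gene_locus(t, promoter_flank_bp), t.gene_id) for t in tss_records
    )


@dataclass(frozen=True)
class GeneLoopLink:
    """One (gene, differential loop) association.

    ``pet_count`` is taken from the side where the loop exists (treated for
    gained, control for lost); ``anchor_hit`` records which anchor(s) of the
    representative loop overlapped the gene locus.
    """

    gene_id: str
    direction: str
    loop_key: BinKey
    loop_status: str
    pet_count: int
    anchor_hit: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if _DIRECTION_FOR_STATUS.get(self.loop_status) != self.direction:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with status {self.loop_status!r}"
            )


def link_genes_to_loops(
    up: Sequence[DEGRecord],
    down: Sequence[DEGRecord],
    diffs: Sequence[DifferentialLoop],
    locus_index: IntervalIndex,
    min_link_pets: int = 5,
) -> List[GeneLoopLink]:
    """Enumerate all direction-consistent gene-loop associations.

    A link exists iff a gene locus overlaps >= 1 anchor of a gained (up
    gene) or lost (down gene) loop whose existing-side PET count is at
    least ``min_link_pets``. Unchanged loops never link. A gene may link to
    many loops and vice versa. Output is sorted (gene_id, loop key).
    """
    degs_by_direction: Dict[str, Dict[str, DEGRecord]] = {
        UP: {d.gene_id: d for d in up},
        DOWN: {d.gene_id: d for d in down},
    }
    links: List[GeneLoopLink] = []
    for diff in diffs:
        direction = _DIRECTION_FOR_STATUS.get(diff.status)
        if direction is None:
            continue
        if diff.existing_side.pet_count < min_link_pets:
            continue
        candidates = degs_by_direction[direction]
        rep = diff.existing_side.representative
        hits: Dict[str, List[str]] = {}
        for label, anchor in (("anchor1", rep.anchor1), ("anchor2", rep.anchor2)):
            for gene_id in locus_index.query(anchor):
                if gene_id in candidates:
                    hits.setdefault(gene_id, []).append(label)
        for gene_id, labels in hits.items():
            deg = candidates[gene_id]
            links.append(
                GeneLoopLink(
                    gene_id=gene_id,
                    direction=direction,
                    loop_key=diff.key,
                    loop_status=diff.status,
                    pet_count=diff.existing_side.pet_count,
                    anchor_hit="+".join(sorted(set(labels))),
                    log2fc=deg.log2fc,
                    padj=deg.padj,
                )
            )
    links.sort(key=lambda ln: (ln.gene_id, ln.loop_key))
    return links


def rank_linked_genes(links: Sequence[GeneLoopLink], direction: str | None = None) -> pd.DataFrame:
    """Unique linked genes ordered by padj ascending.

    Ties on padj are broken by |log2fc| descending, then gene_id ascending.
    Pass ``direction`` ("up"/"down") to rank one direction only.
    """
    by_gene: Dict[str, dict] = {}
    for ln in links:
        if direction is not None and ln.direction != direction:
            continue
        entry = by_gene.setdefault(
            ln.gene_id,
            {"gene_id": ln.gene_id, "direction": ln.direction,
             "log2fc": ln.log2fc, "padj": ln.padj, "n_links": 0},
        )
        entry["n_links"] += 1
    ordered = sorted(
        by_gene.values(),
        key=lambda e: (e["padj"], -abs(e["log2fc"]), e["gene_id"]),
    )
    return pd.DataFrame(
        ordered, columns=["gene_id", "direction", "log2fc", "padj", "n_links"]
    )


def links_frame(links: Sequence[GeneLoopLink]) -> pd.DataFrame:
    """Flat gene-loop link table for TSV output."""
    rows = [
        {
            "gene_id": ln.gene_id,
            "direction": ln.direction,
            "chrom": ln.loop_key[0],
            "bin1": ln.loop_key[1],
            "bin2": ln.loop_key[2],
            "loop_status": ln.loop_status,
            "pet_count": ln.pet_count,
            "anchor_hit": ln.anchor_hit,
            "log2fc": ln.log2fc,
            "padj": ln.padj,
        }
        for ln in links
    ]
    columns = [
        "gene_id", "direction", "chrom", "bin1", "bin2",
        "loop_status", "pet_count", "anchor_hit", "log2fc", "padj",
    ]
    return pd.DataFrame(rows, columns=columns)
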