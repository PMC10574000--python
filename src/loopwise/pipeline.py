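"""End-to-end orchestration: read -> filter -> normalize -> classify ->
match -> call differential -> select DEGs -> link -> rank -> write tables."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import pandas as pd

from . import __version__
from .connectome import classified_frame, classify_loops, summarize_connectome
from .differential import (
    annotate_differential,
    call_differential,
    differential_frame,
    filter_loops,
    match_loops,
    normalize,
    summarize_differential,
)
from .genome import build_index, promoter_window
from .integration import (
    build_locus_index,
    link_genes_to_loops,
    links_frame,
    rank_linked_genes,
)
from .io_formats import (
    RunConfig,
    read_bed_peaks,
    read_bedpe,
    read_de_table,
    read_gtf_tss,
    sort_loop_frame,
    write_tables,
)

log = logging.getLogger("loopwise")


@dataclass
class RunReport:
    """Record counts, thresholds and headline summaries of one run."""

    thresholds: Dict[str, float]
    seed: int
    version: str
    counts: Dict[str, int] = field(default_factory=dict)
    connectome: Dict[str, dict] = field(default_factory=dict)
    n_linked_up: int = 0
    n_linked_down: int = 0
    top_up_genes: List[str] = field(default_factory=list)
    top_down_genes: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


@dataclass
class PipelineResult:
    """In-memory results of a run alongside the report and written files."""

    report: RunReport
    diffs: list
    links: list
    ranked_up: pd.DataFrame
    ranked_down: pd.DataFrame
    tables: Dict[str, pd.DataFrame]
    files: Dict[str, Path]


def run_pipeline(config: RunConfig, top_k: int = 10) -> PipelineResult:
    """Execute the full analysis described by ``config`` and write all outputs."""
    t0 = time.perf_counter()
    cfg = config

    # stage: read
    control = read_bedpe(cfg.control_bedpe, "control", cfg.control_total_valid_pairs)
    treated = read_bedpe(cfg.treated_bedpe, "treated", cfg.treated_total_valid_pairs)
    peaks = read_bed_peaks(cfg.peaks_bed)
    tss_records = read_gtf_tss(cfg.genes_gtf)
    de_table = read_de_table(cfg.de_table)
    log.info("read %d control / %d treated loops, %d peaks, %d genes, %d DE rows",
             len(control), len(treated), len(peaks), len(tss_records), len(de_table))

    # stage: filter + normalize
    control_f = filter_loops(control, cfg.fdr_max, cfg.min_pets)
    treated_f = filter_loops(treated, cfg.fdr_max, cfg.min_pets)
    control_n = normalize(control_f)
    treated_n = normalize(treated_f)

    # stage: annotate + classify per condition
    promoter_index = build_index(
        (promoter_window(t, cfg.promoter_flank_bp), t.gene_id) for t in tss_records
    )
    peak_index = build_index(
        (p.interval, p.name or str(p.interval)) for p in peaks
    )
    classified_control = classify_loops(control_f.loops, promoter_index, peak_index)
    classified_treated = classify_loops(treated_f.loops, promoter_index, peak_index)
    summary_control = summarize_connectome(classified_control, cfg.long_range_bp)
    summary_treated = summarize_connectome(classified_treated, cfg.long_range_bp)

    # stage: match + differential
    pairs = match_loops(control_n, treated_n, cfg.match_bin_bp)
    diffs = call_differential(pairs, cfg.strength_fold)
    annotate_differential(
        diffs,
        {c.loop.loop_id: c for c in classified_control},
        {c.loop.loop_id: c for c in classified_treated},
    )
    diff_summary = summarize_differential(diffs, cfg.long_range_bp)

    # stage: DEG selection + linking + ranking
    up, down = select_degs_from(de_table, cfg)
    locus_index = build_locus_index(tss_records, cfg.promoter_flank_bp)
    links = link_genes_to_loops(up, down, diffs, locus_index, cfg.min_link_pets)
    ranked_up = rank_linked_genes(links, direction="up")
    ranked_down = rank_linked_genes(links, direction="down")

    # stage: write
    conn_frames = []
    for label, summ in (("control", summary_control), ("treated", summary_treated)):
        frame = summ.to_frame()
        frame.insert(0, "condition", label)
        conn_frames.append(frame)
    tables = {
        "classified_control": sort_loop_frame(classified_frame(classified_control)),
        "classified_treated": sort_loop_frame(classified_frame(classified_treated)),
        "connectome_summary": pd.concat(conn_frames, ignore_index=True),
        "differential_loops": differential_frame(diffs),
        "differential_summary": diff_summary,
        "gene_loop_links": links_frame(links),
        "ranked_genes_up": ranked_up,
        "ranked_genes_down": ranked_down,
    }
    files = write_tables(tables, cfg.out_dir)

    report = RunReport(
        thresholds={
            "fdr_max": cfg.fdr_max,
            "min_pets": cfg.min_pets,
            "strength_fold": cfg.strength_fold,
            "up_log2fc_min": cfg.up_log2fc_min,
            "down_log2fc_max": cfg.down_log2fc_max,
            "padj_max": cfg.padj_max,
            "long_range_bp": cfg.long_range_bp,
            "promoter_flank_bp": cfg.promoter_flank_bp,
            "match_bin_bp": cfg.match_bin_bp,
            "min_link_pets": cfg.min_link_pets,
        },
        seed=cfg.seed,
        version=__version__,
        counts={
            "control_loops_read": len(control),
            "treated_loops_read": len(treated),
            "control_loops_kept": len(control_f),
            "treated_loops_kept": len(treated_f),
            "matched_pairs": len(pairs),
            "gained": sum(1 for d in diffs if d.status == "gained"),
            "lost": sum(1 for d in diffs if d.status == "lost"),
            "unchanged": sum(1 for d in diffs if d.status == "unchanged"),
            "degs_up": len(up),
            "degs_down": len(down),
            "links": len(links),
        },
        connectome={
            "control": {"counts": summary_control.counts,
                        "percentages": summary_control.percentages},
            "treated": {"counts": summary_treated.counts,
                        "percentages": summary_treated.percentages},
        },
        n_linked_up=len(ranked_up),
        n_linked_down=len(ranked_down),
        top_up_genes=list(ranked_up["gene_id"].head(top_k)),
        top_down_genes=list(ranked_down["gene_id"].head(top_k)),
    )
    report_path = Path(cfg.out_dir) / "report.json"
    report_path.write_text(report.to_json() + "\n")
    files["report"] = report_path
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return PipelineResult(report, diffs, links, ranked_up, ranked_down, tables, files)


def select_degs_from(de_table, cfg: RunConfig):
    from .integration import select_degs

    return select_degs(de_table, cfg.up_log2fc_min, cfg.down_log2fc_max, cfg.padj_max)
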