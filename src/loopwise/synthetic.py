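"""Seeded two-condition synthetic bundles with known ground truth.

The generator emulates the statistical structure of an H3K27ac HiChIP
two-condition comparison: a simulated gene annotation and enhancer peak set,
two BEDPE loop lists sharing a backbone of stable loops plus planted
gained/lost changes (in number and in strength), decoy loops that fail the
FDR/PET filters, and a differential-expression table whose planted up/down
genes are coupled to planted loop changes at their loci.

Count model: each loop has a per-loop baseline strength drawn from a
negative binomial (over-dispersion across loops, the dominant feature of
contact counts); condition-level raw counts are the baseline scaled by
sequencing depth with small multiplicative log-normal jitter. The fold-
change caller downstream has no replicates, so its validity presumes
technical noise well below ``strength_fold``; the generator encodes exactly
that regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .genome import GenomicInterval, Peak, TSSRecord
from .io_formats import LoopRecord, LoopSet, RunConfig, make_loop, write_bedpe

ANCHOR_HALF_BP = 1_000  # planted anchors are feature centre +/- 1 kb

BinKey = Tuple[str, int, int]


class PlacementError(RuntimeError):
    """Config demands more planted loops than available anchor pairs."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe a small genome (3 chromosomes x 10 Mb) dense enough to
    carry 200 genes, 300 enhancer peaks and ~660 loops: 500 stable, 50/50
    gained/lost in number, 30/30 changed in strength at a true fold of 2,
    PET counts around a mean of 15, plus decoys exercising both filters.
    """

    n_chromosomes: int = 3
    chrom_length_bp: int = 10_000_000
    n_genes: int = 200
    n_peaks: int = 300
    n_stable_loops: int = 500
    n_gained_number: int = 50
    n_lost_number: int = 50
    n_gained_strength: int = 30
    n_lost_strength: int = 30
    strength_true_fold: float = 2.0
    pet_mean: float = 15.0
    pet_dispersion: float = 8.0  # NB size parameter; var = m + m^2/size
    jitter_log2_sd: float = 0.1  # between-condition technical noise
    control_total_valid_pairs: int = 1_200_000
    treated_total_valid_pairs: int = 1_000_000
    null_log2fc_sd: float = 0.3
    de_effect_size: float = 2.0  # planted |log2FC| floor; must exceed DEG cut
    coupling_fraction: float = 0.6
    n_decoy_fdr: int = 25  # per condition, FDR >= 0.05
    n_decoy_pets: int = 25  # per condition, PETs < 5
    match_bin_bp: int = 5_000
    promoter_flank_bp: int = 2_000
    min_pets: int = 5
    min_distance_bp: int = 15_000
    max_distance_bp: int = 2_000_000
    other_anchor_fraction: float = 0.05  # stable loops with a non-E/P anchor
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length_bp", "n_genes", "n_peaks",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "n_stable_loops", "n_gained_number", "n_lost_number",
            "n_gained_strength", "n_lost_strength", "n_decoy_fdr", "n_decoy_pets",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pet_dispersion <= 0:
            raise ValueError("pet_dispersion must be > 0")
        if self.strength_true_fold <= 1:
            raise ValueError("strength_true_fold must be > 1")
        if not (0.0 <= self.coupling_fraction <= 1.0):
            raise ValueError("coupling_fraction must be in [0,1]")
        if self.de_effect_size <= 1.0:
            raise ValueError("de_effect_size must exceed the DEG |log2FC| cut of 1")


@dataclass
class SimulationTruth:
    """Ground truth of one bundle, keyed by match-resolution bin keys."""

    gained_keys: Set[BinKey] = field(default_factory=set)
    lost_keys: Set[BinKey] = field(default_factory=set)
    mode_by_key: Dict[BinKey, str] = field(default_factory=dict)
    fold_by_key: Dict[BinKey, float] = field(default_factory=dict)
    up_genes: List[str] = field(default_factory=list)
    down_genes: List[str] = field(default_factory=list)
    coupled_up: Dict[str, BinKey] = field(default_factory=dict)
    coupled_down: Dict[str, BinKey] = field(default_factory=dict)


def draw_pet_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Negative-binomial PET counts with the given mean and size parameter."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------


def _anchor(chrom: str, center: int, length: int) -> GenomicInterval:
    start = max(0, center - ANCHOR_HALF_BP)
    end = min(length, center + ANCHOR_HALF_BP)
    return GenomicInterval(chrom, start, end)


class _Placer:
    """Samples feature pairs for loop anchors under bin-key uniqueness."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator,
                 promoters: Dict[str, List[Tuple[int, str]]],
                 enhancers: Dict[str, List[int]]):
        self.cfg = cfg
        self.rng = rng
        self.promoters = promoters
        self.enhancers = enhancers
        self.chroms = sorted(promoters)
        self.used_keys: Set[BinKey] = set()

    def _key(self, c1: int, c2: int, chrom: str) -> BinKey:
        lo, hi = sorted((c1, c2))
        return (chrom, lo // self.cfg.match_bin_bp, hi // self.cfg.match_bin_bp)

    def _ok(self, c1: int, c2: int) -> bool:
        d = abs(c1 - c2)
        return self.cfg.min_distance_bp <= d <= self.cfg.max_distance_bp

    def take(self, key: BinKey) -> None:
        self.used_keys.add(key)

    def pair(self, kind: str, gene_id: Optional[str] = None,
             max_attempts: int = 5_000) -> Tuple[str, int, int, Optional[str]]:
        """Return (chrom, center1, center2, promoter_gene_id) for a loop of
        anchor kind 'EPI', 'EEI', 'PPI' or 'other'; reserves the bin key.

        When ``gene_id`` is given (coupled EPI loop) the promoter anchor is
        that gene's TSS.
        """
        cfg, rng = self.cfg, self.rng
        for _ in range(max_attempts):
            if gene_id is not None:
                chrom, tss = self._gene_pos(gene_id)
                cands = self.enhancers.get(chrom, [])
                if not cands:
                    break
                other = cands[rng.integers(len(cands))]
                c1, c2, pg = tss, other, gene_id
            else:
                chrom = self.chroms[rng.integers(len(self.chroms))]
                proms = self.promoters.get(chrom, [])
                enhs = self.enhancers.get(chrom, [])
                if kind == "EPI":
                    if not proms or not enhs:
                        continue
                    tss, pg = proms[rng.integers(len(proms))]
                    c1, c2 = tss, enhs[rng.integers(len(enhs))]
                elif kind == "EEI":
                    if len(enhs) < 2:
                        continue
                    i, j = rng.choice(len(enhs), size=2, replace=False)
                    c1, c2, pg = enhs[i], enhs[j], None
                elif kind == "PPI":
                    if len(proms) < 2:
                        continue
                    i, j = rng.choice(len(proms), size=2, replace=False)
                    c1, c2 = proms[i][0], proms[j][0]
                    pg = proms[i][1]
                else:  # 'other': one random non-feature position
                    if not enhs:
                        continue
                    c1 = enhs[rng.integers(len(enhs))]
                    c2 = int(rng.integers(ANCHOR_HALF_BP, cfg.chrom_length_bp - ANCHOR_HALF_BP))
                    pg = None
            if not self._ok(c1, c2):
                continue
            key = self._key(c1, c2, chrom)
            if key in self.used_keys:
                continue
            self.used_keys.add(key)
            return chrom, c1, c2, pg
        raise PlacementError(
            f"could not place a {kind} loop pair"
            + (f" for gene {gene_id}" if gene_id else "")
            + "; config demands more planted loops than available anchor pairs"
        )

    def _gene_pos(self, gene_id: str) -> Tuple[str, int]:
        for chrom, proms in self.promoters.items():
            for tss, gid in proms:
                if gid == gene_id:
                    return chrom, tss
        raise KeyError(gene_id)


def _draw_baseline(rng: np.random.Generator, cfg: SimulationConfig, floor: int) -> float:
    return float(max(floor, draw_pet_counts(rng, cfg.pet_mean, cfg.pet_dispersion, 1)[0]))


def _raw_count(rng: np.random.Generator, cfg: SimulationConfig,
               strength: float, total_valid_pairs: int, floor: int) -> int:
    depth = total_valid_pairs / 1e6
    jitter = 2.0 ** rng.normal(0.0, cfg.jitter_log2_sd)
    return max(floor, int(round(strength * depth * jitter)))


def simulate_bundle(
    config: SimulationConfig, out_dir: str | Path
) -> Tuple[SimulationTruth, RunConfig]:
    """Write a complete input bundle and return its ground truth.

    Outputs under ``out_dir``: ``genes.gtf``, ``peaks.bed``,
    ``control.bedpe``, ``treated.bedpe``, ``de_table.tsv``,
    ``truth_loops.tsv``, ``truth_genes.tsv`` and ``run_config.yaml`` (a
    ready-to-run pipeline configuration). Fully reproducible from
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    L = cfg.chrom_length_bp

    # --- genes -------------------------------------------------------------
    genes: List[TSSRecord] = []
    for i in range(cfg.n_genes):
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        start = int(rng.integers(100_000, L - 200_000))
        glen = int(rng.integers(5_000, 40_000))
        strand = "+" if rng.random() < 0.5 else "-"
        body = GenomicInterval(chrom, start, start + glen)
        tss = body.start if strand == "+" else body.end - 1
        genes.append(TSSRecord(f"GENE{i + 1:04d}", chrom, tss, strand, body))
    promoters: Dict[str, List[Tuple[int, str]]] = {c: [] for c in chroms}
    prom_windows: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for g in genes:
        promoters[g.chrom].append((g.tss, g.gene_id))
        prom_windows[g.chrom].append(
            (max(0, g.tss - cfg.promoter_flank_bp), g.tss + cfg.promoter_flank_bp)
        )
    for c in chroms:
        promoters[c].sort()
        prom_windows[c].sort()

    # --- enhancer peaks (kept clear of promoter windows) --------------------
    margin = ANCHOR_HALF_BP + 200
    peaks: List[Peak] = []
    enhancers: Dict[str, List[int]] = {c: [] for c in chroms}
    attempts = 0
    while len(peaks) < cfg.n_peaks:
        attempts += 1
        if attempts > 100 * cfg.n_peaks:
            raise PlacementError("could not place enhancer peaks away from promoters")
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        width = int(rng.integers(400, 1_500))
        start = int(rng.integers(50_000, L - 50_000 - width))
        end = start + width
        if any(start - margin < we and ws < end + margin for ws, we in prom_windows[chrom]):
            continue
        signal = float(np.round(rng.gamma(2.0, 10.0), 3))
        peaks.append(Peak(GenomicInterval(chrom, start, end),
                          signal=signal, name=f"peak{len(peaks) + 1:04d}"))
        enhancers[chrom].append((start + end) // 2)
    for c in chroms:
        enhancers[c].sort()

    placer = _Placer(cfg, rng, promoters, enhancers)
    truth = SimulationTruth()
    control_loops: List[LoopRecord] = []
    treated_loops: List[LoopRecord] = []

    def _fdr_pass() -> float:
        return float(np.round(rng.uniform(1e-6, 0.04), 6))

    def _add(side: List[LoopRecord], chrom: str, c1: int, c2: int,
             pets: int, fdr: float) -> LoopRecord:
        loop = make_loop(_anchor(chrom, c1, L), _anchor(chrom, c2, L), pets, fdr)
        side.append(loop)
        return loop

    def _plant_changes(n_number: int, n_strength: int, status: str,
                       coupled_genes: List[str]) -> None:
        """Plant n_number one-sided and n_strength fold-changed loops."""
        present = treated_loops if status == "gained" else control_loops
        absent_fold = cfg.strength_true_fold
        specs = [("number", i) for i in range(n_number)] + [
            ("strength", i) for i in range(n_strength)
        ]
        gene_iter = iter(coupled_genes)
        for mode, _ in specs:
            gene = next(gene_iter, None)
            if gene is not None:
                chrom, c1, c2, _pg = placer.pair("EPI", gene_id=gene)
            else:
                kind = "EPI" if rng.random() < 0.5 else "EEI"
                chrom, c1, c2, _pg = placer.pair(kind)
            key = placer._key(c1, c2, chrom)
            if mode == "number":
                floor = max(cfg.min_pets, 5)
                base = _draw_baseline(rng, cfg, floor)
                tvp = (cfg.treated_total_valid_pairs if status == "gained"
                       else cfg.control_total_valid_pairs)
                _add(present, chrom, c1, c2,
                     _raw_count(rng, cfg, base, tvp, floor), _fdr_pass())
                truth.fold_by_key[key] = math.inf
            else:
                base = _draw_baseline(rng, cfg, max(cfg.min_pets, 10))
                lo, hi = base, base * absent_fold
                ctrl_s, trt_s = (lo, hi) if status == "gained" else (hi, lo)
                _add(control_loops, chrom, c1, c2,
                     _raw_count(rng, cfg, ctrl_s, cfg.control_total_valid_pairs,
                                cfg.min_pets), _fdr_pass())
                _add(treated_loops, chrom, c1, c2,
                     _raw_count(rng, cfg, trt_s, cfg.treated_total_valid_pairs,
                                cfg.min_pets), _fdr_pass())
                truth.fold_by_key[key] = absent_fold
            (truth.gained_keys if status == "gained" else truth.lost_keys).add(key)
            truth.mode_by_key[key] = mode
            if gene is not None:
                if status == "gained":
                    truth.coupled_up[gene] = key
                else:
                    truth.coupled_down[gene] = key

    # --- coupled DEGs -------------------------------------------------------
    n_gained = cfg.n_gained_number + cfg.n_gained_strength
    n_lost = cfg.n_lost_number + cfg.n_lost_strength
    n_coup_up = int(round(cfg.coupling_fraction * n_gained))
    n_coup_down = int(round(cfg.coupling_fraction * n_lost))
    if n_coup_up + n_coup_down > cfg.n_genes:
        raise PlacementError("coupling demands more genes than simulated")
    # a coupled gene needs >= 1 enhancer within the loop-distance window
    def _n_eligible(g: TSSRecord) -> int:
        return sum(
            1 for e in enhancers[g.chrom]
            if cfg.min_distance_bp <= abs(e - g.tss) <= cfg.max_distance_bp
        )

    shuffled = [g.gene_id for g in genes if _n_eligible(g) > 0]
    rng.shuffle(shuffled)
    if n_coup_up + n_coup_down > len(shuffled):
        raise PlacementError(
            "coupling demands more genes with reachable enhancers than simulated"
        )
    coup_up = shuffled[:n_coup_up]
    coup_down = shuffled[n_coup_up:n_coup_up + n_coup_down]
    truth.up_genes = sorted(coup_up)
    truth.down_genes = sorted(coup_down)

    _plant_changes(cfg.n_gained_number, cfg.n_gained_strength, "gained", coup_up)
    _plant_changes(cfg.n_lost_number, cfg.n_lost_strength, "lost", coup_down)

    # --- stable backbone ----------------------------------------------------
    kinds = ["EEI", "EPI", "PPI", "other"]
    probs = np.array([0.55, 0.30, 0.10, cfg.other_anchor_fraction])
    probs = probs / probs.sum()
    for _ in range(cfg.n_stable_loops):
        kind = kinds[int(rng.choice(4, p=probs))]
        chrom, c1, c2, _pg = placer.pair(kind)
        base = _draw_baseline(rng, cfg, cfg.min_pets)
        _add(control_loops, chrom, c1, c2,
             _raw_count(rng, cfg, base, cfg.control_total_valid_pairs, cfg.min_pets),
             _fdr_pass())
        _add(treated_loops, chrom, c1, c2,
             _raw_count(rng, cfg, base, cfg.treated_total_valid_pairs, cfg.min_pets),
             _fdr_pass())

    # --- decoys: always included, always filtered out -----------------------
    for side, tvp in ((control_loops, cfg.control_total_valid_pairs),
                      (treated_loops, cfg.treated_total_valid_pairs)):
        for _ in range(cfg.n_decoy_fdr):
            chrom, c1, c2, _pg = placer.pair("EEI")
            base = _draw_baseline(rng, cfg, cfg.min_pets)
            _add(side, chrom, c1, c2, _raw_count(rng, cfg, base, tvp, cfg.min_pets),
                 float(np.round(rng.uniform(0.05, 0.5), 6)))
        for _ in range(cfg.n_decoy_pets):
            chrom, c1, c2, _pg = placer.pair("EEI")
            _add(side, chrom, c1, c2, int(rng.integers(1, cfg.min_pets)), _fdr_pass())

    # --- DE table ------------------------------------------------------------
    planted = {g: "up" for g in coup_up}
    planted.update({g: "down" for g in coup_down})
    de_rows: List[Tuple[str, str, str]] = []
    null_ids = [g.gene_id for g in genes if g.gene_id not in planted]
    na_ids = set(null_ids[:2])  # exercise the missing-padj drop path
    for g in genes:
        gid = g.gene_id
        if gid in planted:
            sign = 1.0 if planted[gid] == "up" else -1.0
            fc = sign * (cfg.de_effect_size + abs(rng.normal(0.0, 0.5)))
            padj = 10.0 ** (-float(rng.uniform(8, 150)))
            de_rows.append((gid, f"{fc:.4f}", f"{padj:.6g}"))
        elif gid in na_ids:
            de_rows.append((gid, f"{rng.normal(0.0, cfg.null_log2fc_sd):.4f}", "NA"))
        else:
            fc = rng.normal(0.0, cfg.null_log2fc_sd)
            padj = float(rng.uniform(0.1, 1.0))
            de_rows.append((gid, f"{fc:.4f}", f"{padj:.6g}"))
    de_rows.sort()

    # --- write bundle ---------------------------------------------------------
    _write_gtf(genes, out_dir / "genes.gtf")
    _write_peaks(peaks, out_dir / "peaks.bed")
    write_bedpe(LoopSet("control", control_loops, cfg.control_total_valid_pairs),
                out_dir / "control.bedpe")
    write_bedpe(LoopSet("treated", treated_loops, cfg.treated_total_valid_pairs),
                out_dir / "treated.bedpe")
    with open(out_dir / "de_table.tsv", "w") as fh:
        fh.write("gene_id\tlog2fc\tpadj\n")
        for row in de_rows:
            fh.write("\t".join(row) + "\n")
    _write_truth(truth, out_dir)

    run_config = RunConfig(
        control_bedpe=str(out_dir / "control.bedpe"),
        treated_bedpe=str(out_dir / "treated.bedpe"),
        peaks_bed=str(out_dir / "peaks.bed"),
        genes_gtf=str(out_dir / "genes.gtf"),
        de_table=str(out_dir / "de_table.tsv"),
        control_total_valid_pairs=cfg.control_total_valid_pairs,
        treated_total_valid_pairs=cfg.treated_total_valid_pairs,
        match_bin_bp=cfg.match_bin_bp,
        promoter_flank_bp=cfg.promoter_flank_bp,
        min_pets=cfg.min_pets,
        seed=cfg.seed,
        out_dir=str(out_dir / "results"),
    )
    run_config.to_yaml(out_dir / "run_config.yaml")
    return truth, run_config


def _write_gtf(genes: Sequence[TSSRecord], path: Path) -> None:
    rows = sorted(genes, key=lambda g: (g.chrom, g.gene_body.start, g.gene_id))
    with open(path, "w") as fh:
        for g in rows:
            fh.write(
                f"{g.chrom}\tloopwise_sim\tgene\t{g.gene_body.start + 1}\t"
                f"{g.gene_body.end}\t.\t{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )


def _write_peaks(peaks: Sequence[Peak], path: Path) -> None:
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.name or '.'}\t{p.signal:g}\n"
            )


def _write_truth(truth: SimulationTruth, out_dir: Path) -> None:
    with open(out_dir / "truth_loops.tsv", "w") as fh:
        fh.write("chrom\tbin1\tbin2\tstatus\tmode\ttrue_fold\n")
        rows = [(k, "gained") for k in truth.gained_keys] + [
            (k, "lost") for k in truth.lost_keys
        ]
        for key, status in sorted(rows):
            fold = truth.fold_by_key[key]
            fh.write(
                f"{key[0]}\t{key[1]}\t{key[2]}\t{status}\t"
                f"{truth.mode_by_key[key]}\t{'inf' if math.isinf(fold) else f'{fold:g}'}\n"
            )
    with open(out_dir / "truth_genes.tsv", "w") as fh:
        fh.write("gene_id\tdirection\tloop_chrom\tbin1\tbin2\n")
        rows2 = [(g, "up", truth.coupled_up[g]) for g in truth.up_genes] + [
            (g, "down", truth.coupled_down[g]) for g in truth.down_genes
        ]
        for gid, direction, key in sorted(rows2):
            fh.write(f"{gid}\t{direction}\t{key[0]}\t{key[1]}\t{key[2]}\n")


# ---------------------------------------------------------------------------
# worked fixture
# ---------------------------------------------------------------------------


def make_worked_fixture(out_dir: str | Path) -> RunConfig:
    """Write a hand-sized, fully deterministic bundle plus golden outputs.

    Six genes on one 10 Mb chromosome; four mimic published ferroptosis
    expression changes (an HDM2-like strongly upregulated gene coupled to a
    new enhancer-promoter loop, a TXNRD1-like gene with a strengthened loop,
    and MKI67-/TOP2A-like downregulated genes losing promoter loops, the
    last two tied at padj = 0 so ranking falls through to |log2FC|). One
    stable enhancer-enhancer loop and two decoys (high FDR; low PETs)
    exercise the unchanged path and both filters. Golden pipeline outputs
    are regenerated under ``<out_dir>/golden``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom, L = "chr1", 10_000_000

    genes = [
        TSSRecord("HDM2", chrom, 1_000_000, "+", GenomicInterval(chrom, 1_000_000, 1_040_000)),
        TSSRecord("TXNRD1", chrom, 2_000_000, "+", GenomicInterval(chrom, 2_000_000, 2_030_000)),
        TSSRecord("MKI67", chrom, 3_049_999, "-", GenomicInterval(chrom, 3_000_000, 3_050_000)),
        TSSRecord("TOP2A", chrom, 4_000_000, "+", GenomicInterval(chrom, 4_000_000, 4_035_000)),
        TSSRecord("NULLA", chrom, 5_000_000, "+", GenomicInterval(chrom, 5_000_000, 5_020_000)),
        TSSRecord("NULLB", chrom, 6_014_999, "-", GenomicInterval(chrom, 6_000_000, 6_015_000)),
    ]
    peak_spans = [
        (1_050_000, 1_051_000), (2_100_000, 2_101_000), (2_200_000, 2_201_000),
        (3_100_000, 3_101_000), (3_200_000, 3_201_000), (4_100_000, 4_101_000),
        (7_000_000, 7_001_000), (7_100_000, 7_101_000), (8_000_000, 8_001_000),
        (8_050_000, 8_051_000), (8_200_000, 8_201_000), (8_300_000, 8_301_000),
    ]
    peaks = [
        Peak(GenomicInterval(chrom, s, e), signal=10.0, name=f"E{i + 1}")
        for i, (s, e) in enumerate(peak_spans)
    ]
    mid = lambda span: (span[0] + span[1]) // 2  # noqa: E731

    def lp(c1: int, c2: int, pets: int, fdr: float) -> LoopRecord:
        return make_loop(_anchor(chrom, c1, L), _anchor(chrom, c2, L), pets, fdr)

    control = [
        lp(2_000_000, mid(peak_spans[1]), 10, 0.001),   # TXNRD1 EPI, strengthens
        lp(3_049_999, mid(peak_spans[3]), 15, 0.001),   # MKI67 EPI, lost
        lp(3_049_999, mid(peak_spans[4]), 9, 0.002),    # MKI67 EPI, lost
        lp(4_000_000, mid(peak_spans[5]), 11, 0.001),   # TOP2A EPI, lost
        lp(mid(peak_spans[6]), mid(peak_spans[7]), 10, 0.01),   # stable EEI
        lp(mid(peak_spans[8]), mid(peak_spans[9]), 3, 0.001),   # decoy: PETs < 5
    ]
    treated = [
        lp(1_000_000, mid(peak_spans[0]), 12, 0.001),   # HDM2 EPI, gained in number
        lp(2_000_000, mid(peak_spans[1]), 24, 0.001),   # TXNRD1 EPI, gained in strength
        lp(2_000_000, mid(peak_spans[2]), 8, 0.003),    # TXNRD1 EPI, gained in number
        lp(mid(peak_spans[6]), mid(peak_spans[7]), 10, 0.01),   # stable EEI
        lp(mid(peak_spans[10]), mid(peak_spans[11]), 20, 0.2),  # decoy: FDR >= 0.05
    ]
    _write_gtf(genes, out_dir / "genes.gtf")
    _write_peaks(peaks, out_dir / "peaks.bed")
    write_bedpe(LoopSet("control", control, 1_000_000), out_dir / "control.bedpe")
    write_bedpe(LoopSet("treated", treated, 1_000_000), out_dir / "treated.bedpe")
    with open(out_dir / "de_table.tsv", "w") as fh:
        fh.write("gene_id\tlog2fc\tpadj\n")
        fh.write("HDM2\t2.44\t2.91e-239\n")
        fh.write("TXNRD1\t2.04\t1.26e-216\n")
        fh.write("MKI67\t-3.89\t0\n")
        fh.write("TOP2A\t-3.31\t0\n")
        fh.write("NULLA\t0.10\t0.9\n")
        fh.write("NULLB\t-0.20\tNA\n")

    cfg = RunConfig(
        control_bedpe=str(out_dir / "control.bedpe"),
        treated_bedpe=str(out_dir / "treated.bedpe"),
        peaks_bed=str(out_dir / "peaks.bed"),
        genes_gtf=str(out_dir / "genes.gtf"),
        de_table=str(out_dir / "de_table.tsv"),
        control_total_valid_pairs=1_000_000,
        treated_total_valid_pairs=1_000_000,
        out_dir=str(out_dir / "golden"),
    )
    cfg.to_yaml(out_dir / "run_config.yaml")

    from .pipeline import run_pipeline  # deferred: pipeline imports are heavier

    run_pipeline(cfg)
    return cfg


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


def evaluate_recovery(truth: SimulationTruth, diffs, ranked_up, ranked_down) -> Dict[str, float]:
    """Sensitivity/precision of gained/lost calls and coupled-DEG link recovery.

    ``diffs`` is the list of DifferentialLoop calls; ``ranked_up`` /
    ``ranked_down`` the ranked linked-gene DataFrames.
    """
    called_gained = {d.key for d in diffs if d.status == "gained"}
    called_lost = {d.key for d in diffs if d.status == "lost"}

    def _sens(called: Set[BinKey], planted: Set[BinKey]) -> float:
        return len(called & planted) / len(planted) if planted else float("nan")

    def _prec(called: Set[BinKey], planted: Set[BinKey]) -> float:
        return len(called & planted) / len(called) if called else float("nan")

    linked_up = set(ranked_up["gene_id"]) if len(ranked_up) else set()
    linked_down = set(ranked_down["gene_id"]) if len(ranked_down) else set()
    coupled = set(truth.coupled_up) | set(truth.coupled_down)
    recovered = (set(truth.coupled_up) & linked_up) | (set(truth.coupled_down) & linked_down)
    return {
        "gained_sensitivity": _sens(called_gained, truth.gained_keys),
        "gained_precision": _prec(called_gained, truth.gained_keys),
        "lost_sensitivity": _sens(called_lost, truth.lost_keys),
        "lost_precision": _prec(called_lost, truth.lost_keys),
        "coupled_deg_link_recovery": (
            len(recovered) / len(coupled) if coupled else float("nan")
        ),
    }
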