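"""Readers and writers for BEDPE loops, BED peaks, GTF genes and TSV tables.

Parsing is strict: malformed numeric fields raise with the offending line
number rather than being coerced. All writers emit deterministically sorted
TSV so repeated runs on identical input are byte-identical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import pandas as pd
import yaml

from .genome import GenomicInterval, Peak, TSSRecord

log = logging.getLogger("loopwise")


class ParseError(ValueError):
    """A malformed input line; message carries the file and line number."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoopRecord:
    """One cis chromatin loop: two anchors, PET support, and loop-call FDR.

    Anchors are canonically ordered so that ``(anchor1.start, anchor1.end)``
    <= ``(anchor2.start, anchor2.end)`` lexicographically.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int
    fdr: float
    loop_id: str

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(f"trans loop not allowed: {self.loop_id}")
        if (self.anchor1.start, self.anchor1.end) > (self.anchor2.start, self.anchor2.end):
            raise ValueError(f"anchors not in canonical order: {self.loop_id}")
        if self.pet_count < 0:
            raise ValueError(f"pet_count must be >= 0: {self.loop_id}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must be in [0,1]: {self.loop_id}")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom


def make_loop(
    anchor1: GenomicInterval,
    anchor2: GenomicInterval,
    pet_count: int,
    fdr: float,
    loop_id: str | None = None,
) -> LoopRecord:
    """Construct a loop with anchors swapped into canonical order.

    When ``loop_id`` is None an id is derived deterministically from the
    (canonical) coordinates.
    """
    if (anchor1.start, anchor1.end) > (anchor2.start, anchor2.end):
        anchor1, anchor2 = anchor2, anchor1
    if loop_id is None:
        loop_id = (
            f"{anchor1.chrom}:{anchor1.start}-{anchor1.end}"
            f"|{anchor2.start}-{anchor2.end}"
        )
    return LoopRecord(anchor1, anchor2, pet_count, fdr, loop_id)


@dataclass
class LoopSet:
    """All loops called in one condition plus its library-size denominator."""

    condition: str
    loops: List[LoopRecord]
    total_valid_pairs: int

    def __post_init__(self) -> None:
        if not self.condition:
            raise ValueError("condition label must be non-empty")
        if self.total_valid_pairs <= 0:
            raise ValueError(f"total_valid_pairs must be > 0, got {self.total_valid_pairs}")
        total_pets = sum(lp.pet_count for lp in self.loops)
        if self.total_valid_pairs < total_pets:
            raise ValueError(
                "total_valid_pairs must be >= sum of loop PET counts "
                f"({self.total_valid_pairs} < {total_pets})"
            )
        seen: set = set()
        for lp in self.loops:
            if lp.loop_id in seen:
                raise ValueError(f"duplicate loop_id: {lp.loop_id}")
            seen.add(lp.loop_id)

    def __len__(self) -> int:
        return len(self.loops)


@dataclass(frozen=True)
class DEGRecord:
    """One gene's expression change: log2 fold change and adjusted p-value.

    ``padj`` may be exactly 0 (as printed by DE tools for extreme genes) and
    is preserved as-is, never floored, because downstream ranking honours it.
    """

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj must be in [0,1] for {self.gene_id}, got {self.padj}")


@dataclass
class RunConfig:
    """Thresholds, paths and seed for a pipeline run.

    Threshold defaults follow the printed analysis settings (loop FDR < 0.05,
    PETs >= 5, |log2FC| thresholds at 1, padj < 0.05, long-range > 20 kb,
    linking PETs >= 5); the genuinely under-specified knobs (strength_fold,
    match_bin_bp, promoter_flank_bp) are explicit and configurable.
    """

    fdr_max: float = 0.05
    min_pets: int = 5
    strength_fold: float = 1.5
    up_log2fc_min: float = 1.0
    down_log2fc_max: float = -1.0
    padj_max: float = 0.05
    long_range_bp: int = 20_000
    promoter_flank_bp: int = 2_000
    match_bin_bp: int = 5_000
    min_link_pets: int = 5
    seed: int = 0

    control_bedpe: str = ""
    treated_bedpe: str = ""
    peaks_bed: str = ""
    genes_gtf: str = ""
    de_table: str = ""
    control_total_valid_pairs: int = 0
    treated_total_valid_pairs: int = 0
    out_dir: str = "loopwise_out"

    def __post_init__(self) -> None:
        for name in ("fdr_max", "padj_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0,1], got {v}")
        for name in (
            "min_pets",
            "long_range_bp",
            "promoter_flank_bp",
            "match_bin_bp",
            "min_link_pets",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.strength_fold <= 1.0:
            raise ValueError(f"strength_fold must be > 1, got {self.strength_fold}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _split_data_lines(path: str | Path):
    """Yield (lineno, fields) for data lines, skipping comments/track lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split("\t")


def _to_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what}: {value!r}") from None


def _to_float(value: str, path, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric {what}: {value!r}") from None


def read_bedpe(
    path: str | Path,
    condition: str,
    total_valid_pairs: int,
    *,
    pet_column: int = 7,
    fdr_column: int = 8,
) -> LoopSet:
    """Read a loop-caller BEDPE into a :class:`LoopSet`.

    Default dialect: columns 1-6 are the two anchors, column 7 a name,
    column 8 (score) the PET count and column 9 the FDR; ``pet_column`` /
    ``fdr_column`` (0-based) remap other dialects. Trans-chromosomal lines
    are dropped with a logged count; anchors are swapped into canonical
    order; loop ids are derived deterministically from coordinates.
    """
    if total_valid_pairs <= 0:
        raise ValueError(f"total_valid_pairs must be > 0, got {total_valid_pairs}")
    loops: List[LoopRecord] = []
    seen_ids: Dict[str, int] = {}
    n_trans = 0
    for lineno, fields in _split_data_lines(path):
        if len(fields) <= max(pet_column, fdr_column):
            raise ParseError(f"{path}:{lineno}: expected >= {max(pet_column, fdr_column) + 1} columns, got {len(fields)}")
        c1, s1, e1, c2, s2, e2 = fields[:6]
        start1 = _to_int(s1, path, lineno, "start1")
        end1 = _to_int(e1, path, lineno, "end1")
        start2 = _to_int(s2, path, lineno, "start2")
        end2 = _to_int(e2, path, lineno, "end2")
        if c1 != c2:
            n_trans += 1
            continue
        pets = _to_int(fields[pet_column], path, lineno, "pet_count")
        fdr = _to_float(fields[fdr_column], path, lineno, "fdr")
        try:
            loop = make_loop(
                GenomicInterval(c1, start1, end1),
                GenomicInterval(c2, start2, end2),
                pets,
                fdr,
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        # disambiguate exact coordinate duplicates deterministically
        n_prev = seen_ids.get(loop.loop_id, 0)
        seen_ids[loop.loop_id] = n_prev + 1
        if n_prev:
            loop = replace(loop, loop_id=f"{loop.loop_id}#{n_prev + 1}")
        loops.append(loop)
    if n_trans:
        log.info("%s: dropped %d trans-chromosomal loop line(s)", path, n_trans)
    loopset = LoopSet(condition=condition, loops=loops, total_valid_pairs=total_valid_pairs)
    loopset.n_trans_dropped = n_trans  # type: ignore[attr-defined]
    return loopset


def write_bedpe(loopset: LoopSet, path: str | Path) -> None:
    """Write a LoopSet in the dialect :func:`read_bedpe` reads (round-trip safe)."""
    rows = sorted(
        loopset.loops,
        key=lambda lp: (_chrom_key(lp.chrom), lp.anchor1.start, lp.anchor2.start, lp.loop_id),
    )
    with open(path, "w") as fh:
        for lp in rows:
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\t"
                f"{lp.loop_id}\t{lp.pet_count}\t{lp.fdr:g}\n"
            )


def read_bed_peaks(path: str | Path) -> List[Peak]:
    """Read a BED3+ peak file; column 5 (score), when present, becomes the signal."""
    peaks: List[Peak] = []
    for lineno, fields in _split_data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
        chrom = fields[0]
        start = _to_int(fields[1], path, lineno, "start")
        end = _to_int(fields[2], path, lineno, "end")
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        signal = _to_float(fields[4], path, lineno, "score") if len(fields) > 4 else 0.0
        peaks.append(Peak(GenomicInterval(chrom, start, end), signal=signal, name=name))
    return peaks


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gtf_tss(path: str | Path, feature: str = "gene") -> List[TSSRecord]:
    """Extract one TSSRecord per gene from a GTF.

    GTF is 1-based inclusive; coordinates are converted to 0-based half-open.
    The TSS is the gene-body start for + strand and the last base (``end-1``
    after conversion) for - strand. Falls back to ``transcript`` features if
    no ``gene`` feature exists.
    """
    for feat in (feature, "transcript"):
        records = _read_gtf_feature(path, feat)
        if records:
            return records
    return []


def _read_gtf_feature(path: str | Path, feature: str) -> List[TSSRecord]:
    records: List[TSSRecord] = []
    seen: set = set()
    for lineno, fields in _split_data_lines(path):
        if len(fields) < 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
        if fields[2] != feature:
            continue
        chrom, start1, end1, strand, attrs = fields[0], fields[3], fields[4], fields[6], fields[8]
        m = _GENE_ID_RE.search(attrs)
        if m is None:
            raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
        gene_id = m.group(1)
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        start = _to_int(start1, path, lineno, "start") - 1  # 1-based -> 0-based
        end = _to_int(end1, path, lineno, "end")  # inclusive -> half-open
        body = GenomicInterval(chrom, start, end)
        tss = start if strand == "+" else end - 1
        records.append(TSSRecord(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand, gene_body=body))
    return records


def read_de_table(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
) -> List[DEGRecord]:
    """Read a differential-expression TSV into DEGRecords.

    ``columns`` maps the required logical names (gene_id, log2fc, padj) to
    the file's header names. Rows with missing padj are dropped with a
    logged count; padj values of exactly 0 are preserved.
    """
    colmap = {"gene_id": "gene_id", "log2fc": "log2fc", "padj": "padj"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s): {missing}")
    n_before = len(df)
    df = df.dropna(subset=[colmap["padj"], colmap["log2fc"]])
    n_dropped = n_before - len(df)
    if n_dropped:
        log.info("%s: dropped %d row(s) with missing padj/log2fc", path, n_dropped)
    records = [
        DEGRecord(
            gene_id=str(row[colmap["gene_id"]]),
            log2fc=float(row[colmap["log2fc"]]),
            padj=float(row[colmap["padj"]]),
        )
        for row in df.to_dict("records")
    ]
    seen: set = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
    return records


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_CHROM_RE = re.compile(r"^(chr)?(\d+|[A-Za-z]+)$")


def _chrom_key(chrom: str):
    """Natural chromosome sort key: chr1 < chr2 < ... < chr10 < chrX."""
    m = _CHROM_RE.match(chrom)
    if m and m.group(2).isdigit():
        return (0, int(m.group(2)), "")
    return (1, 0, chrom)


def sort_loop_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic output order: chrom (natural), anchor1 start, anchor2 start."""
    if df.empty:
        return df
    cols = [c for c in ("chrom", "a1_start", "a2_start", "loop_id") if c in df.columns]
    key = df["chrom"].map(_chrom_key) if "chrom" in df.columns else None
    out = df.assign(_ck=key) if key is not None else df.copy()
    sort_cols = (["_ck"] if key is not None else []) + [c for c in cols if c != "chrom"]
    out = out.sort_values(sort_cols, kind="mergesort").drop(columns=["_ck"], errors="ignore")
    return out.reset_index(drop=True)


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> Dict[str, Path]:
    """Write each named DataFrame as ``<out_dir>/<name>.tsv``.

    Output is deterministic: callers pre-sort rows (see
    :func:`sort_loop_frame`); floats are rendered with repr-round-tripping
    precision so identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written[name] = path
    return written
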