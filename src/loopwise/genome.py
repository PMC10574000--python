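"""Core genomic-interval types and overlap-query index.

All coordinates are 0-based, half-open ``[start, end)``, matching BED/BEDPE.
GTF input (1-based, inclusive) is converted on read by :mod:`loopwise.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, List, Tuple

from intervaltree import IntervalTree


class InvalidIntervalError(ValueError):
    """Raised when an interval violates ``0 <= start < end`` or lacks a chromosome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)`` in bp."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvalidIntervalError("chromosome name must be non-empty")
        if self.start < 0:
            raise InvalidIntervalError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise InvalidIntervalError(
                f"start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint in bp."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TSSRecord:
    """A gene's transcription start site plus its gene body span.

    ``tss`` is the 0-based position of the first transcribed base; for a
    minus-strand gene this is the right edge of the gene body.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.gene_body.start <= self.tss <= self.gene_body.end):
            raise ValueError(
                f"TSS {self.tss} outside gene body {self.gene_body} for {self.gene_id}"
            )
        if self.chrom != self.gene_body.chrom:
            raise ValueError(f"chrom mismatch for {self.gene_id}")


@dataclass(frozen=True)
class Peak:
    """An enrichment peak (here: H3K27ac, marking candidate enhancers/promoters)."""

    interval: GenomicInterval
    signal: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def promoter_window(tss: TSSRecord, flank: int = 2000) -> GenomicInterval:
    """Strand-symmetric promoter window ``[tss - flank, tss + flank)``, clamped at 0.

    The window is deliberately strand-independent: a symmetric +/- ``flank``
    around the TSS is the conventional promoter proxy when no asymmetric
    definition is given.
    """
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    return GenomicInterval(tss.chrom, max(0, tss.tss - flank), tss.tss + flank)


@dataclass
class IntervalIndex:
    """Per-chromosome overlap index over (interval, payload) pairs.

    A query returns exactly the payloads whose intervals overlap the query
    by >= 1 bp under half-open semantics — identical to an exhaustive scan.
    """

    _trees: dict = field(default_factory=dict)
    _n: int = 0

    def __len__(self) -> int:
        return self._n

    def add(self, interval: GenomicInterval, payload: Any) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, payload)
        self._n += 1

    def query(self, interval: GenomicInterval) -> List[Any]:
        """Payloads of all indexed intervals overlapping ``interval``."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval.start, interval.end)]

    def any_overlap(self, interval: GenomicInterval) -> bool:
        tree = self._trees.get(interval.chrom)
        return tree is not None and tree.overlaps(interval.start, interval.end)


def build_index(items: Iterable[Tuple[GenomicInterval, Any]]) -> IntervalIndex:
    """Build an :class:`IntervalIndex` from (interval, payload) pairs.

    Intervals are validated by construction of :class:`GenomicInterval`; a
    malformed tuple raises :class:`InvalidIntervalError` naming the record.
    """
    index = IntervalIndex()
    for interval, payload in items:
        if not isinstance(interval, GenomicInterval):
            raise InvalidIntervalError(f"not a GenomicInterval: {interval!r}")
        index.add(interval, payload)
    return index
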