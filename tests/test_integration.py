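"""DEG selection, gene loci, gene-loop linking and ranking."""

import numpy as np
import pytest

from loopwise.differential import call_differential, match_loops, normalize
from loopwise.genome import GenomicInterval, TSSRecord, build_index
from loopwise.integration import (
    GeneLoopLink,
    build_locus_index,
    gene_locus,
    link_genes_to_loops,
    rank_linked_genes,
    select_degs,
)
from loopwise.io_formats import DEGRecord, LoopSet, make_loop


def gi(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestSelectDegs:
    @pytest.mark.parametrize("log2fc,padj,direction", [
        (2.44, 2.91e-239, "up"),
        (1.0, 1e-10, None),     # strict > 1 for up
        (-1.0, 1e-10, "down"),  # inclusive <= -1 for down
        (1.5, 0.05, None),      # strict padj < 0.05
        (-3.89, 0.0, "down"),
        (0.5, 0.001, None),
    ])
    def test_printed_threshold_forms(self, log2fc, padj, direction):
        up, down = select_degs([DEGRecord("g", log2fc, padj)])
        got = "up" if up else "down" if down else None
        assert got == direction

    def test_sets_disjoint(self):
        table = [DEGRecord(f"g{i}", fc, 0.001) for i, fc in enumerate((-2.0, -1.0, 0.0, 1.5, 3.0))]
        up, down = select_degs(table)
        assert {d.gene_id for d in up}.isdisjoint({d.gene_id for d in down})


class TestGeneLocus:
    def test_union_of_promoter_and_body(self):
        t = TSSRecord("g", "chr1", 10_000, "+", gi(10_000, 30_000))
        assert gene_locus(t, 2_000) == gi(8_000, 30_000)

    def test_body_inside_window(self):
        t = TSSRecord("g", "chr1", 10_000, "+", gi(10_000, 11_000))
        assert gene_locus(t, 2_000) == gi(8_000, 12_000)

    def test_minus_strand_extends_past_body_end(self):
        t = TSSRecord("g", "chr1", 29_999, "-", gi(10_000, 30_000))
        assert gene_locus(t, 2_000) == gi(10_000, 31_999)


def _diff(status, m1, m2, pets, chrom="chr1"):
    lp = make_loop(gi(m1 - 1_000, m1 + 1_000, chrom), gi(m2 - 1_000, m2 + 1_000, chrom), pets, 0.001)
    side = normalize(LoopSet("x", [lp], 1_000_000))
    pairs = match_loops(side, [], 5_000) if status == "lost" else match_loops([], side, 5_000)
    (d,) = call_differential(pairs)
    return d


class TestLinkGenesToLoops:
    GENE = TSSRecord("gUP", "chr1", 100_000, "+", gi(100_000, 120_000))
    UP = [DEGRecord("gUP", 2.0, 1e-5)]
    DOWN = [DEGRecord("gDN", -2.0, 1e-5)]

    def _index(self, *tss):
        return build_locus_index(tss or [self.GENE], 2_000)

    def test_promoter_anchor_overlap_links(self):
        d = _diff("gained", 100_000, 160_000, pets=12)
        links = link_genes_to_loops(self.UP, [], [d], self._index(), 5)
        assert [ln.gene_id for ln in links] == ["gUP"]
        assert links[0].anchor_hit == "anchor1"

    def test_pet_threshold_boundary(self):
        d4 = _diff("gained", 100_000, 160_000, pets=4)
        d5 = _diff("gained", 100_000, 160_000, pets=5)
        assert link_genes_to_loops(self.UP, [], [d4], self._index(), 5) == []
        assert len(link_genes_to_loops(self.UP, [], [d5], self._index(), 5)) == 1

    def test_direction_consistency(self):
        gained = _diff("gained", 100_000, 160_000, pets=12)
        down_gene = [DEGRecord("gUP", -2.0, 1e-5)]  # same locus, wrong direction
        assert link_genes_to_loops([], down_gene, [gained], self._index(), 5) == []

    def test_unchanged_loops_never_link(self):
        lp = make_loop(gi(99_000, 101_000), gi(159_000, 161_000), 12, 0.001)
        side = normalize(LoopSet("x", [lp], 1_000_000))
        (d,) = call_differential(match_loops(side, side, 5_000))
        assert d.status == "unchanged"
        assert link_genes_to_loops(self.UP, [], [d], self._index(), 5) == []

    def test_monotonic_in_min_link_pets(self):
        diffs = [_diff("gained", 100_000, 160_000, pets=p) for p in (5, 8, 12)]
        n_prev = None
        for thr in (5, 8, 12, 13):
            n = len(link_genes_to_loops(self.UP, [], diffs, self._index(), thr))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        """Link set equals the triple loop over (genes x diffs x anchors)."""
        from loopwise.genome import overlaps
        from loopwise.integration import gene_locus as locus

        rng = np.random.default_rng(seed)
        tss_records, degs = [], []
        for i in range(50):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(10_000, 900_000))
            t = TSSRecord(f"g{i}", chrom, start, "+", gi(start, start + int(rng.integers(2_000, 30_000)), chrom))
            tss_records.append(t)
            degs.append(DEGRecord(f"g{i}", float(rng.normal(0, 2)), float(rng.uniform(0, 0.1))))
        up, down = select_degs(degs)
        diffs = []
        for i in range(60):
            chrom = f"chr{rng.integers(1, 3)}"
            m1 = int(rng.integers(5_000, 800_000))
            m2 = m1 + int(rng.integers(15_000, 150_000))
            status = "gained" if rng.random() < 0.5 else "lost"
            diffs.append(_diff(status, m1, m2, pets=int(rng.integers(1, 20)), chrom=chrom))
        idx = build_locus_index(tss_records, 2_000)
        got = {(ln.gene_id, ln.loop_key) for ln in link_genes_to_loops(up, down, diffs, idx, 5)}
        expected = set()
        by_dir = {"gained": {d.gene_id for d in up}, "lost": {d.gene_id for d in down}}
        for t in tss_records:
            for d in diffs:
                if d.status not in by_dir or t.gene_id not in by_dir[d.status]:
                    continue
                if d.existing_side.pet_count < 5:
                    continue
                rep = d.existing_side.representative
                if overlaps(locus(t, 2_000), rep.anchor1) or overlaps(locus(t, 2_000), rep.anchor2):
                    expected.add((t.gene_id, d.key))
        assert got == expected


class TestRankLinkedGenes:
    def _link(self, gene, log2fc, padj, direction="up", key=("chr1", 10, 20)):
        status = "gained" if direction == "up" else "lost"
        return GeneLoopLink(gene, direction, key, status, 10, "anchor1", log2fc, padj)

    def test_ranked_by_padj(self):
        links = [self._link("TXNRD1", 2.04, 1.26e-216), self._link("HDM2", 2.44, 2.91e-239)]
        assert list(rank_linked_genes(links)["gene_id"]) == ["HDM2", "TXNRD1"]

    def test_padj_zero_tie_broken_by_abs_log2fc(self):
        links = [self._link("TOP2A", -3.31, 0.0, "down"), self._link("MKI67", -3.89, 0.0, "down")]
        assert list(rank_linked_genes(links)["gene_id"]) == ["MKI67", "TOP2A"]

    def test_empty_links_empty_table(self):
        table = rank_linked_genes([])
        assert len(table) == 0

    def test_n_links_aggregates_unique_gene(self):
        links = [self._link("g", 2.0, 1e-5, key=("chr1", 1, 2)),
                 self._link("g", 2.0, 1e-5, key=("chr1", 3, 4))]
        table = rank_linked_genes(links)
        assert len(table) == 1 and table["n_links"].item() == 2

    def test_direction_filter(self):
        links = [self._link("u", 2.0, 1e-5, "up"), self._link("d", -2.0, 1e-5, "down")]
        assert list(rank_linked_genes(links, "up")["gene_id"]) == ["u"]
        assert list(rank_linked_genes(links, "down")["gene_id"]) == ["d"]

    def test_direction_inconsistent_link_rejected(self):
        with pytest.raises(ValueError):
            GeneLoopLink("g", "up", ("chr1", 1, 2), "lost", 10, "anchor1", 2.0, 1e-5)
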