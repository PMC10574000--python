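"""Filtering, normalization, cross-condition matching and gained/lost calls."""

import math

import numpy as np
import pytest

from loopwise.connectome import classify_loop, AnchorAnnotation
from loopwise.differential import (
    GAINED,
    LOST,
    UNCHANGED,
    MODE_NUMBER,
    MODE_STRENGTH,
    NormalizedLoop,
    annotate_differential,
    bin_key,
    call_differential,
    filter_loops,
    match_loops,
    normalize,
    summarize_differential,
)
from loopwise.genome import GenomicInterval
from loopwise.io_formats import LoopSet, make_loop


def gi(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def loop(a1, a2, pets=10, fdr=0.01, chrom="chr1"):
    return make_loop(gi(*a1, chrom=chrom), gi(*a2, chrom=chrom), pets, fdr)


def loopset(loops, condition="c", total=1_000_000):
    return LoopSet(condition, loops, total)


class TestFilterLoops:
    @pytest.mark.parametrize("fdr,pets,kept", [
        (0.04, 5, True),    # both thresholds met
        (0.05, 100, False),  # FDR boundary: strict <
        (0.001, 4, False),  # PET boundary: at least 5
        (0.049, 5, True),
    ])
    def test_printed_inequality_forms(self, fdr, pets, kept):
        ls = loopset([loop((0, 100), (9_000, 9_100), pets=pets, fdr=fdr)])
        out = filter_loops(ls, fdr_max=0.05, min_pets=5)
        assert (len(out) == 1) is kept
        assert out.n_filtered_out == (0 if kept else 1)


class TestNormalize:
    def test_per_million(self):
        ls = loopset([loop((0, 100), (9_000, 9_100), pets=5)], total=1_000_000)
        assert normalize(ls)[0].norm_count == 5.0

    def test_zero_count(self):
        ls = loopset([loop((0, 100), (9_000, 9_100), pets=0)])
        assert normalize(ls)[0].norm_count == 0.0

    def test_scale_invariance(self):
        ls1 = loopset([loop((0, 100), (9_000, 9_100), pets=5)], total=1_000_000)
        ls2 = loopset([loop((0, 100), (9_000, 9_100), pets=10)], total=2_000_000)
        assert normalize(ls1)[0].norm_count == normalize(ls2)[0].norm_count


def norm(loops, total=1_000_000):
    return normalize(loopset(loops, total=total))


class TestMatchLoops:
    def test_identical_loops_pair_up(self):
        c = norm([loop((0, 2_000), (50_000, 52_000))])
        t = norm([loop((0, 2_000), (50_000, 52_000))])
        (pair,) = match_loops(c, t, 5_000)
        assert pair.control is not None and pair.treated is not None

    def test_far_shifted_loop_is_one_sided(self):
        c = norm([loop((0, 2_000), (50_000, 52_000))])
        t = norm([loop((20_000, 22_000), (90_000, 92_000))])
        pairs = match_loops(c, t, 5_000)
        assert len(pairs) == 2
        assert all((p.control is None) != (p.treated is None) for p in pairs)

    def test_small_shift_within_bin_matches(self):
        c = norm([loop((0, 2_000), (50_000, 52_000))])
        t = norm([loop((1_000, 3_000), (51_000, 53_000))])  # mids shift 1 kb
        (pair,) = match_loops(c, t, 5_000)
        assert pair.control and pair.treated

    def test_same_bin_loops_aggregate_by_sum(self):
        c = norm([loop((0, 2_000), (50_000, 52_000), pets=4),
                  loop((500, 2_500), (50_500, 52_500), pets=6)])
        (pair,) = match_loops(c, [], 5_000)
        assert pair.control.pet_count == 10
        assert pair.control.norm_count == pytest.approx(10.0)
        assert pair.control.representative.pet_count == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_bin_pairing(self, seed):
        rng = np.random.default_rng(seed)

        def rand_loops(n):
            out = []
            for _ in range(n):
                chrom = f"chr{rng.integers(1, 3)}"
                m1 = int(rng.integers(1_000, 200_000))
                m2 = m1 + int(rng.integers(10_000, 100_000))
                out.append(loop((m1 - 1_000, m1 + 1_000), (m2 - 1_000, m2 + 1_000),
                                pets=int(rng.integers(5, 30)), chrom=chrom))
            return out

        c, t = norm(rand_loops(100)), norm(rand_loops(100))
        pairs = match_loops(c, t, 5_000)
        # brute force: group by key independently and compare membership
        expected = {}
        for side, nls in (("c", c), ("t", t)):
            for nl in nls:
                expected.setdefault(bin_key(nl.loop, 5_000), {"c": [], "t": []})[side].append(nl)
        assert {p.key for p in pairs} == set(expected)
        for p in pairs:
            exp = expected[p.key]
            got_c = p.control.loops if p.control else []
            got_t = p.treated.loops if p.treated else []
            assert sorted(nl.loop.loop_id for nl in got_c) == sorted(nl.loop.loop_id for nl in exp["c"])
            assert sorted(nl.loop.loop_id for nl in got_t) == sorted(nl.loop.loop_id for nl in exp["t"])
        # every input loop contributes to exactly one pair
        assert sum(len(p.control.loops) if p.control else 0 for p in pairs) == len(c)


def _pairs(control_loops, treated_loops, ct=1_000_000, tt=1_000_000):
    return match_loops(norm(control_loops, ct), norm(treated_loops, tt), 5_000)


class TestCallDifferential:
    def test_treated_only_is_gained_in_number(self):
        (d,) = call_differential(_pairs([], [loop((0, 2_000), (50_000, 52_000))]))
        assert (d.status, d.mode) == (GAINED, MODE_NUMBER)

    def test_control_only_is_lost_in_number(self):
        (d,) = call_differential(_pairs([loop((0, 2_000), (50_000, 52_000))], []))
        assert (d.status, d.mode) == (LOST, MODE_NUMBER)

    def test_fold_change_is_gained_in_strength(self):
        (d,) = call_differential(_pairs(
            [loop((0, 2_000), (50_000, 52_000), pets=4)],
            [loop((0, 2_000), (50_000, 52_000), pets=10)],
        ), strength_fold=1.5)
        assert (d.status, d.mode) == (GAINED, MODE_STRENGTH)
        assert d.log2_ratio == pytest.approx(math.log2(2.5))

    def test_equal_counts_unchanged(self):
        (d,) = call_differential(_pairs(
            [loop((0, 2_000), (50_000, 52_000), pets=6)],
            [loop((0, 2_000), (50_000, 52_000), pets=6)],
        ))
        assert (d.status, d.mode) == (UNCHANGED, "none")
        assert d.log2_ratio == pytest.approx(0.0)

    def test_invalid_strength_fold_rejected(self):
        with pytest.raises(ValueError):
            call_differential([], strength_fold=1.0)

    def test_conservation_and_antisymmetry(self):
        rng = np.random.default_rng(3)
        c_loops, t_loops = [], []
        for i in range(60):
            m1 = 10_000 + 20_000 * i
            m2 = m1 + 40_000
            lp_c = loop((m1 - 1_000, m1 + 1_000), (m2 - 1_000, m2 + 1_000),
                        pets=int(rng.integers(5, 40)))
            lp_t = loop((m1 - 1_000, m1 + 1_000), (m2 - 1_000, m2 + 1_000),
                        pets=int(rng.integers(5, 40)))
            if rng.random() < 0.8:
                c_loops.append(lp_c)
            if rng.random() < 0.8:
                t_loops.append(lp_t)
        fwd = call_differential(_pairs(c_loops, t_loops))
        rev = call_differential(_pairs(t_loops, c_loops))
        n = {s: sum(1 for d in fwd if d.status == s) for s in (GAINED, LOST, UNCHANGED)}
        assert sum(n.values()) == len(fwd)  # conservation over matched pairs
        by_key_fwd = {d.key: d for d in fwd}
        by_key_rev = {d.key: d for d in rev}
        assert set(by_key_fwd) == set(by_key_rev)
        swap = {GAINED: LOST, LOST: GAINED, UNCHANGED: UNCHANGED}
        for key, d in by_key_fwd.items():
            r = by_key_rev[key]
            assert r.status == swap[d.status]
            if math.isfinite(d.log2_ratio):
                assert r.log2_ratio == pytest.approx(-d.log2_ratio)

    def test_scale_invariance_of_status_calls(self):
        c = [loop((0, 2_000), (50_000, 52_000), pets=6),
             loop((100_000, 102_000), (200_000, 202_000), pets=10)]
        t = [loop((0, 2_000), (50_000, 52_000), pets=6),
             loop((100_000, 102_000), (200_000, 202_000), pets=30)]
        base = call_differential(_pairs(c, t))
        scaled_c = [make_loop(l.anchor1, l.anchor2, l.pet_count * 3, l.fdr) for l in c]
        scaled = call_differential(_pairs(scaled_c, t, ct=3_000_000))
        assert [d.status for d in base] == [d.status for d in scaled]


def _ann(cls):
    return AnchorAnnotation(gi(0, 100), cls, ())


class TestSummarizeDifferential:
    def _diff_with_category(self, category, status, distance, idx):
        m1 = 10_000 + 50_000 * idx
        lp = loop((m1 - 1_000, m1 + 1_000), (m1 + distance - 1_000, m1 + distance + 1_000))
        pairs = _pairs([lp], []) if status == LOST else _pairs([], [lp])
        (d,) = call_differential(pairs)
        cls_map = {"EEI": ("enhancer", "enhancer"), "EPI": ("enhancer", "promoter"),
                   "PPI": ("promoter", "promoter"), "other": ("other", "other")}[category]
        cl = classify_loop(lp, _ann(cls_map[0]), _ann(cls_map[1]))
        lookup = {lp.loop_id: cl}
        annotate_differential([d], lookup, lookup)
        return d

    def test_totals_are_category_sums(self):
        diffs = []
        idx = 0
        for cat, n in (("EEI", 4), ("EPI", 3), ("PPI", 2)):
            for _ in range(n):
                diffs.append(self._diff_with_category(cat, GAINED, 40_000, idx))
                idx += 1
        for cat, n in (("EEI", 2), ("PPI", 1)):
            for _ in range(n):
                diffs.append(self._diff_with_category(cat, LOST, 15_000, idx))
                idx += 1
        table = summarize_differential(diffs, long_range_bp=20_000)
        gained_total = table[(table.status == GAINED) & (table.category == "total")]["count"].item()
        lost_total = table[(table.status == LOST) & (table.category == "total")]["count"].item()
        assert gained_total == 9 and lost_total == 3
        gained_lr = table[(table.status == GAINED) & (table.category == "total")]["long_range_count"].item()
        assert gained_lr == 9  # all at 40 kb > 20 kb
        lost_lr = table[(table.status == LOST) & (table.category == "total")]["long_range_count"].item()
        assert lost_lr == 0

    def test_empty_input_all_zero(self):
        table = summarize_differential([])
        assert (table["count"] == 0).all()
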