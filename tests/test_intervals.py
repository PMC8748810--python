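"""Interval algebra, BED I/O, replicate consensus and promoter windows."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from g4scape.intervals import (
    BedParseError,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    k_of_n_consensus,
    merge,
    overlap_count,
    overlap_percent,
    promoter_windows,
    read_bed,
    venn3_counts,
    write_bed,
)

from conftest import (
    TOY_CHROM_LEN,
    iset,
    per_base_coverage,
    random_interval_pairs,
    runs_of_true,
)


# --------------------------------------------------------------------- I/O


class TestBedIO:
    def test_minimal_record(self, tmp_path, toy_assembly):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\n")
        s = read_bed(p, toy_assembly)
        assert [(iv.chrom, iv.start, iv.end) for iv in s] == [("chr1", 0, 10)]

    def test_empty_file(self, tmp_path, toy_assembly):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p, toy_assembly)) == 0

    def test_unsorted_input_round_trips_sorted(self, tmp_path, toy_assembly):
        rng = np.random.default_rng(11)
        pairs = random_interval_pairs(rng, 50, TOY_CHROM_LEN)
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        p = tmp_path / "u.bed"
        p.write_text("".join(f"chr1\t{s}\t{e}\n" for s, e in shuffled))
        s1 = read_bed(p, toy_assembly)
        # independent sort of the raw tuples
        expected = sorted(shuffled)
        assert [(iv.start, iv.end) for iv in s1] == expected
        # write/read round-trip is byte-identical after sorting
        out1, out2 = tmp_path / "r1.bed", tmp_path / "r2.bed"
        write_bed(s1, out1)
        write_bed(read_bed(out1, toy_assembly), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_malformed_line_reports_line_number(self, tmp_path, toy_assembly):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\nchr1\tfoo\t20\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p, toy_assembly)

    def test_unknown_chrom_named_in_error(self, tmp_path, toy_assembly):
        p = tmp_path / "bad.bed"
        p.write_text("chrXX\t0\t10\n")
        with pytest.raises(BedParseError, match="chrXX"):
            read_bed(p, toy_assembly)

    def test_comment_and_track_lines_skipped(self, tmp_path, toy_assembly):
        p = tmp_path / "c.bed"
        p.write_text("# seed=3\ntrack name=x\nchr1\t5\t9\n")
        assert len(read_bed(p, toy_assembly)) == 1


# --------------------------------------------------------------------- merge


class TestMerge:
    def test_overlapping(self, toy_assembly):
        m = merge(iset([(0, 10), (5, 15)], toy_assembly))
        assert [(iv.start, iv.end) for iv in m] == [(0, 15)]

    def test_book_ended_intervals_join(self, toy_assembly):
        m = merge(iset([(0, 5), (5, 10)], toy_assembly))
        assert [(iv.start, iv.end) for iv in m] == [(0, 10)]

    def test_covered_bp_matches_per_base_oracle(self, toy_assembly):
        rng = np.random.default_rng(7)
        s = iset(random_interval_pairs(rng, 200, TOY_CHROM_LEN), toy_assembly)
        oracle = int(per_base_coverage([s], "chr1", TOY_CHROM_LEN).astype(bool).sum())
        assert merge(s).total_bp() == oracle
        assert s.total_bp() == oracle

    @given(st.lists(st.tuples(st.integers(0, 9000), st.integers(1, 500)), max_size=30))
    def test_idempotent_and_coverage_preserving(self, raw):
        assembly = {"chr1": TOY_CHROM_LEN}
        pairs = [(s, min(TOY_CHROM_LEN, s + w)) for s, w in raw]
        s = iset(pairs, assembly)
        m = merge(s)
        assert merge(m) == m
        assert m.total_bp() == s.total_bp()
        # disjoint and non-adjacent
        for a, b in zip(m.intervals, m.intervals[1:]):
            assert a.end < b.start


# --------------------------------------------------------------------- consensus


class TestConsensus:
    def test_hand_example(self, toy_assembly):
        a = iset([(0, 10)], toy_assembly, "a")
        b = iset([(5, 15)], toy_assembly, "b")
        c = iset([(20, 30)], toy_assembly, "c")
        res = k_of_n_consensus([a, b, c], 2)
        assert [(iv.start, iv.end) for iv in res] == [(5, 10)]

    def test_k1_is_union(self, toy_assembly):
        rng = np.random.default_rng(3)
        sets = [
            iset(random_interval_pairs(rng, 30, TOY_CHROM_LEN), toy_assembly, str(i))
            for i in range(3)
        ]
        union = merge(
            IntervalSet(
                [iv for s in sets for iv in s], toy_assembly, "u"
            )
        )
        assert k_of_n_consensus(sets, 1) == union

    def test_errors(self, toy_assembly):
        with pytest.raises(ValueError):
            k_of_n_consensus([], 1)
        a = iset([(0, 10)], toy_assembly)
        with pytest.raises(ValueError):
            k_of_n_consensus([a], 2)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 3))
    def test_matches_per_base_oracle(self, seed, k):
        """Sweep-line result == threshold on literal per-base coverage depth."""
        assembly = {"chr1": TOY_CHROM_LEN}
        rng = np.random.default_rng(seed)
        sets = [
            iset(random_interval_pairs(rng, 50, TOY_CHROM_LEN), assembly, str(i))
            for i in range(3)
        ]
        depth = per_base_coverage(sets, "chr1", TOY_CHROM_LEN)
        expected = runs_of_true(depth >= k)
        got = [(iv.start, iv.end) for iv in k_of_n_consensus(sets, k)]
        assert got == expected

    def test_monotone_in_k(self, toy_assembly):
        rng = np.random.default_rng(5)
        sets = [
            iset(random_interval_pairs(rng, 40, TOY_CHROM_LEN), toy_assembly, str(i))
            for i in range(3)
        ]
        cov = None
        prev_bp = None
        for k in (1, 2, 3):
            res = k_of_n_consensus(sets, k)
            bp = res.total_bp()
            if prev_bp is not None:
                assert bp <= prev_bp
            # coverage subset: every base of level k+1 is covered at level k
            mask = per_base_coverage([res], "chr1", TOY_CHROM_LEN).astype(bool)
            if cov is not None:
                assert not np.any(mask & ~cov)
            cov = mask
            prev_bp = bp


# --------------------------------------------------------------------- overlap


class TestOverlap:
    def test_single_hit(self, toy_assembly):
        a = iset([(0, 10), (20, 30)], toy_assembly, "a")
        b = iset([(5, 6)], toy_assembly, "b")
        assert overlap_count(a, b) == 1
        assert overlap_percent(1, 2) == 50.0

    def test_identity(self, toy_assembly):
        rng = np.random.default_rng(9)
        a = merge(iset(random_interval_pairs(rng, 40, TOY_CHROM_LEN), toy_assembly))
        assert overlap_count(a, a) == len(a)
        assert overlap_percent(len(a), len(a)) == 100.0

    def test_empty_query_flagged(self, toy_assembly):
        a = IntervalSet([], toy_assembly, "a")
        b = iset([(0, 10)], toy_assembly, "b")
        assert overlap_count(a, b) == 0
        assert overlap_percent(0, 0) is None

    def test_duplicates_counted_once(self, toy_assembly):
        a = IntervalSet(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 0, 10)],
            toy_assembly,
            "a",
        )
        b = iset([(5, 6)], toy_assembly, "b")
        assert overlap_count(a, b) == 1


class TestVenn3:
    def test_disjoint(self, toy_assembly):
        a = iset([(0, 10)], toy_assembly, "a")
        b = iset([(20, 30)], toy_assembly, "b")
        c = iset([(40, 50)], toy_assembly, "c")
        v = venn3_counts(a, b, c)
        assert v["100"]["a"] == 1 and v["010"]["b"] == 1 and v["001"]["c"] == 1
        for pattern in ("110", "101", "011", "111"):
            assert all(n == 0 for n in v[pattern].values())

    def test_identical_sets_all_triple(self, toy_assembly):
        a = iset([(0, 10), (20, 30)], toy_assembly, "a")
        v = venn3_counts(a, a, a)
        assert v["111"] == {"a": 2, "b": 2, "c": 2}

    def test_consistent_with_brute_force_membership(self, toy_assembly):
        rng = np.random.default_rng(21)
        sets = {
            lbl: iset(random_interval_pairs(rng, 25, TOY_CHROM_LEN), toy_assembly, lbl)
            for lbl in "abc"
        }
        v = venn3_counts(sets["a"], sets["b"], sets["c"])

        def brute_hits(iv, other):
            return any(iv.overlaps(o) for o in other)

        pos = {"a": 0, "b": 1, "c": 2}
        for lbl in "abc":
            others = [o for o in "abc" if o != lbl]
            tallies = {}
            for iv in sets[lbl].dedup():
                bits = ["0", "0", "0"]
                bits[pos[lbl]] = "1"
                for o in others:
                    if brute_hits(iv, sets[o]):
                        bits[pos[o]] = "1"
                key = "".join(bits)
                tallies[key] = tallies.get(key, 0) + 1
            for pattern, counts in v.items():
                if lbl in counts:
                    assert counts[lbl] == tallies.get(pattern, 0)
            # pairwise consistency: total hits of lbl in o equals overlap_count
            for o in others:
                total = sum(
                    n
                    for pattern, counts in v.items()
                    for l2, n in counts.items()
                    if l2 == lbl and pattern[pos[o]] == "1"
                )
                assert total == overlap_count(sets[lbl], sets[o])


# --------------------------------------------------------------------- promoters


class TestPromoterWindows:
    def test_definition_is_symmetric_inclusive(self, toy_assembly):
        g = GeneModel("g1", "chr1", "+", 5000)
        ws, mapping = promoter_windows([g], toy_assembly, flank=1000)
        assert (mapping["g1"].start, mapping["g1"].end) == (4000, 6001)
        assert len(mapping["g1"]) == 2001

    def test_left_clip(self, toy_assembly):
        g = GeneModel("g1", "chr1", "+", 200)
        _, mapping = promoter_windows([g], toy_assembly, flank=1000)
        assert (mapping["g1"].start, mapping["g1"].end) == (0, 1201)

    def test_minus_strand_window_from_transcript_end(self, toy_assembly):
        # transcript [100, 900) on the minus strand: TSS = 899
        tss = 900 - 1
        g = GeneModel("g1", "chr1", "-", tss)
        _, mapping = promoter_windows([g], toy_assembly, flank=1000)
        # independent strand-flip computation
        assert mapping["g1"].start == max(0, tss - 1000)
        assert mapping["g1"].end == tss + 1001

    def test_tss_outside_chrom_errors(self, toy_assembly):
        g = GeneModel("g1", "chr1", "+", TOY_CHROM_LEN + 5)
        with pytest.raises(ValueError, match="g1"):
            promoter_windows([g], toy_assembly)
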