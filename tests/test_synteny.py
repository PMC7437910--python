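"""Synteny blocks: chaining, thresholds, gene structure, coverage."""
from __future__ import annotations

import numpy as np
import pytest

from refscaf.io_formats import AlignmentSegment
from refscaf.synteny import (
    GeneModel,
    coalesce,
    filter_blocks,
    reference_coverage,
    verify_gene_structure,
)


def _seg(rs, re_, qs, qe, strand="+", ref="chr1", qry="scaf1"):
    return AlignmentSegment(ref, rs, re_, qry, qs, qe, strand)


class TestCoalesce:
    def test_adjacent_colinear_segments_chain(self):
        segs = [_seg(0, 600_000, 0, 600_000), _seg(600_000, 1_200_000, 600_000, 1_200_000)]
        (b,) = coalesce(segs, max_join_gap=50_000)
        assert (b.ref_start, b.ref_end, b.span) == (0, 1_200_000, 1_200_000)
        assert len(b.segments) == 2

    def test_non_monotone_query_order_splits(self):
        segs = [_seg(0, 600_000, 600_000, 1_200_000), _seg(600_000, 1_200_000, 0, 600_000)]
        assert len(coalesce(segs, max_join_gap=50_000)) == 2

    def test_reverse_strand_chains_reverse_monotone(self):
        segs = [_seg(0, 500, 1000, 1500, "-"), _seg(600, 1100, 400, 900, "-")]
        (b,) = coalesce(segs, max_join_gap=1000, min_seg=100)
        assert b.strand == "-"
        assert (b.qry_start, b.qry_end) == (400, 1500)

    @pytest.mark.parametrize("length,kept", [(99, 0), (100, 1), (101, 1)])
    def test_min_segment_filter_boundary(self, length, kept):
        assert len(coalesce([_seg(0, length, 0, length)], 1000)) == kept

    def test_gap_beyond_max_join_splits(self):
        segs = [_seg(0, 1000, 0, 1000), _seg(2001, 3000, 2001, 3000)]
        assert len(coalesce(segs, max_join_gap=1000)) == 2
        assert len(coalesce(segs, max_join_gap=1001)) == 1

    def test_idempotent_on_block_bounds(self):
        rng = np.random.default_rng(15)
        segs = []
        pos = 0
        for i in range(50):
            length = int(rng.integers(100, 5000))
            gap = int(rng.integers(0, 80_000))
            segs.append(_seg(pos + gap, pos + gap + length, pos + gap, pos + gap + length))
            pos += gap + length
        blocks = coalesce(segs, max_join_gap=50_000)
        again = coalesce(
            [_seg(b.ref_start, b.ref_end, b.qry_start, b.qry_end) for b in blocks],
            max_join_gap=0, min_seg=1,
        )
        assert [(b.ref_start, b.ref_end) for b in again] == [
            (b.ref_start, b.ref_end) for b in blocks
        ]

    def test_matches_quadratic_chaining_oracle(self):
        rng = np.random.default_rng(21)
        segs = []
        for i in range(500):
            rs = int(rng.integers(0, 500_000))
            length = int(rng.integers(50, 3000))
            offset = int(rng.integers(-200, 200))
            strand = "+" if rng.random() < 0.7 else "-"
            qs = rs + offset if strand == "+" else 500_000 - rs - length + offset
            segs.append(_seg(rs, rs + length, max(qs, 0), max(qs, 0) + length, strand))
        got = coalesce(segs, max_join_gap=5000, min_seg=100)

        # independent oracle, mirroring the declared chaining semantics
        def oracle(segments, max_gap, min_seg):
            groups = {}
            for s in segments:
                if s.ref_end - s.ref_start < min_seg:
                    continue
                groups.setdefault((s.ref_name, s.qry_name, s.strand), []).append(s)
            blocks = []
            for key in sorted(groups):
                ss = sorted(groups[key], key=lambda s: (s.ref_start, s.ref_end))
                # midpoint-trim overlaps
                trimmed = []
                for s in ss:
                    s = AlignmentSegment(s.ref_name, s.ref_start, s.ref_end,
                                         s.qry_name, s.qry_start, s.qry_end, s.strand)
                    drop = False
                    while trimmed and s.ref_start < trimmed[-1].ref_end:
                        prev = trimmed[-1]
                        ov = prev.ref_end - s.ref_start
                        cut_prev = ov - ov // 2
                        cut_cur = ov - cut_prev
                        prev.ref_end -= cut_prev
                        if prev.strand == "+":
                            prev.qry_end -= cut_prev
                        else:
                            prev.qry_start += cut_prev
                        s.ref_start += cut_cur
                        if s.strand == "+":
                            s.qry_start += cut_cur
                        else:
                            s.qry_end -= cut_cur
                        if prev.ref_end <= prev.ref_start or prev.qry_end <= prev.qry_start:
                            trimmed.pop()
                            continue
                        break
                    if s.ref_end > s.ref_start and s.qry_end > s.qry_start:
                        trimmed.append(s)
                cur = []
                for s in trimmed:
                    if cur:
                        a = cur[-1]
                        rg = s.ref_start - a.ref_end
                        qg = (s.qry_start - a.qry_end) if s.strand == "+" else (a.qry_start - s.qry_end)
                        if 0 <= rg <= max_gap and 0 <= qg <= max_gap:
                            cur.append(s)
                            continue
                        blocks.append(cur)
                        cur = [s]
                    else:
                        cur = [s]
                if cur:
                    blocks.append(cur)
            return [
                (c[0].ref_start, c[-1].ref_end, len(c)) for c in blocks
            ]

        assert [(b.ref_start, b.ref_end, len(b.segments)) for b in got] == oracle(
            segs, 5000, 100
        )


class TestFilterBlocks:
    def _block(self, span):
        (b,) = coalesce([_seg(0, span, 0, span)], 1000, min_seg=1)
        return b

    @pytest.mark.parametrize(
        "span,threshold,kept",
        [
            (900_000, 1_000_000, False),
            (900_000, 500_000, True),
            (1_000_000, 1_000_000, True),
            (999_999, 1_000_000, False),
            (1_000_001, 1_000_000, True),
            (499_999, 500_000, False),
            (500_000, 500_000, True),
            (500_001, 500_000, True),
        ],
    )
    def test_span_threshold_boundary(self, span, threshold, kept):
        assert len(filter_blocks([self._block(span)], threshold)) == (1 if kept else 0)

    def test_zero_threshold_is_identity(self):
        blocks = [self._block(10), self._block(100)]
        assert filter_blocks(blocks, 0) == blocks

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(33)
        blocks = [self._block(int(s)) for s in rng.integers(1000, 2_000_000, 30)]
        sizes = [len(filter_blocks(blocks, t)) for t in (0, 250_000, 500_000, 1_000_000)]
        assert sizes == sorted(sizes, reverse=True)


class TestGeneStructure:
    def test_ordered_plus_strand_verified(self):
        g = GeneModel("g", [("s1", 10, 20, "+"), ("s1", 30, 40, "+"), ("s1", 50, 60, "+")])
        assert verify_gene_structure(g) == "verified"

    def test_two_scaffolds_split(self):
        g = GeneModel("g", [("s1", 10, 20, "+"), ("s2", 30, 40, "+")])
        assert verify_gene_structure(g) == "split"

    def test_reverse_strand_decreasing_is_verified(self):
        g = GeneModel("g", [("s1", 50, 60, "-"), ("s1", 30, 40, "-"), ("s1", 10, 20, "-")])
        assert verify_gene_structure(g) == "verified"

    def test_mixed_strands(self):
        g = GeneModel("g", [("s1", 10, 20, "+"), ("s1", 30, 40, "-")])
        assert verify_gene_structure(g) == "strand_mixed"

    def test_shuffled_exons_disordered(self):
        g = GeneModel("g", [("s1", 30, 40, "+"), ("s1", 10, 20, "+")])
        assert verify_gene_structure(g) == "disordered"

    def test_empty_exons_error(self):
        with pytest.raises(ValueError):
            GeneModel("g", [])


class TestReferenceCoverage:
    def test_full_tiling(self):
        fractions, mean = reference_coverage([("c1", 0, 100)], {"c1": 100})
        assert fractions == {"c1": 1.0} and mean == 1.0

    def test_mean_matches_published_statistic_shape(self):
        fractions, mean = reference_coverage(
            [("c1", 0, 1000), ("c2", 0, 962)], {"c1": 1000, "c2": 1000}
        )
        assert mean == pytest.approx(0.981)

    def test_unknown_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            reference_coverage([("ghost", 0, 10)], {"c1": 100})

    def test_matches_union_oracle(self):
        rng = np.random.default_rng(40)
        ivs = []
        for _ in range(200):
            s = int(rng.integers(0, 900))
            ivs.append(("c1", s, s + int(rng.integers(1, 120))))
        fractions, _ = reference_coverage(ivs, {"c1": 1000})
        covered = set()
        for _, s, e in ivs:
            covered.update(range(s, min(e, 1000)))
        # intervals may exceed the sequence end; union counts raw bp
        covered_raw = set()
        for _, s, e in ivs:
            covered_raw.update(range(s, e))
        assert fractions["c1"] == len(covered_raw) / 1000
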