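"""Scaffolding: link bundling, greedy path-merging, sequence emission."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from refscaf.asm_metrics import assembly_stats, nx_lx
from refscaf.mate_verify import ContigPlacement, LibrarySpec, MateLink, classify_link
from refscaf.scaffolder import (
    BundledEdge,
    bundle_links,
    emit_scaffolds,
    greedy_path_merge,
)

LIB = LibrarySpec("m1k", 1000, 100, "ff")


def _span_link(a, b, end_a="R", end_b="L", gap=100.0, i=0):
    pa = ContigPlacement(f"p{i}/1", a, 0, 1, "+", 1, "mate_first")
    pb = ContigPlacement(f"p{i}/2", b, 0, 1, "+", 1, "mate_second")
    return MateLink(f"p{i}", pa, pb, LIB, "spanning", end_a=end_a, end_b=end_b, gap=gap)


def _edge(a, b, w, end_a="R", end_b="L", gap=100.0, sd=1.0):
    return BundledEdge(a, b, end_a, end_b, w, gap, sd)


class TestBundle:
    def test_mean_and_weight(self):
        links = [_span_link("A", "B", gap=g, i=i) for i, g in enumerate([100, 120, 80, 100])]
        edges, discarded = bundle_links(links)
        (e,) = edges
        assert (e.weight, e.gap_mean) == (4, 100.0)
        assert discarded == 0

    def test_minority_orientation_class_discarded(self):
        links = [_span_link("A", "B", "R", "L", i=i) for i in range(3)]
        links.append(_span_link("A", "B", "R", "R", i=9))
        edges, discarded = bundle_links(links)
        (e,) = edges
        assert (e.end_a, e.end_b, e.weight) == ("R", "L", 3)
        assert discarded == 1

    def test_normalization_orders_pair_lexicographically(self):
        (e,), _ = bundle_links([_span_link("B", "A", "L", "R")])
        assert (e.contig_a, e.contig_b, e.end_a, e.end_b) == ("A", "B", "R", "L")

    def test_matches_group_and_average_oracle(self):
        rng = np.random.default_rng(12)
        names = ["A", "B", "C", "D"]
        links, oracle = [], {}
        for i in range(200):
            a, b = sorted(rng.choice(names, 2, replace=False))
            ends = (rng.choice(["L", "R"]), rng.choice(["L", "R"]))
            gap = float(rng.normal(200, 50))
            links.append(_span_link(a, b, *ends, gap=gap, i=i))
            oracle.setdefault((a, b, *ends), []).append(gap)
        edges, discarded = bundle_links(links)
        kept = 0
        for e in edges:
            gaps = oracle[(e.contig_a, e.contig_b, e.end_a, e.end_b)]
            assert e.weight == len(gaps)
            assert e.gap_mean == pytest.approx(np.mean(gaps))
            assert e.gap_sd == pytest.approx(np.std(gaps, ddof=1))
            kept += e.weight
            best = max(len(v) for k, v in oracle.items() if k[:2] == (e.contig_a, e.contig_b))
            assert e.weight == best
        assert kept + discarded == len(links)


def _accepted_weight(paths, edges):
    """Total weight of edges realized as adjacencies in the paths."""
    adj = set()
    for p in paths:
        for x, y in zip(p.elements, p.elements[1:]):
            ex = "R" if x.orientation == "+" else "L"
            ey = "L" if y.orientation == "+" else "R"
            a, b, ea, eb = x.contig_id, y.contig_id, ex, ey
            if b < a:
                a, b, ea, eb = b, a, eb, ea
            adj.add((a, b, ea, eb))
    return sum(e.weight for e in edges if (e.contig_a, e.contig_b, e.end_a, e.end_b) in adj)


def _exhaustive_optimum(contigs, edges):
    """Best total weight over all feasible edge subsets (vertex-disjoint
    paths: each contig end used at most once, no cycles)."""
    best = 0
    for r in range(len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            used = set()
            parent = {c: c for c in contigs}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            ok = True
            for e in subset:
                ka, kb = (e.contig_a, e.end_a), (e.contig_b, e.end_b)
                if ka in used or kb in used or find(e.contig_a) == find(e.contig_b):
                    ok = False
                    break
                used.update((ka, kb))
                parent[find(e.contig_a)] = find(e.contig_b)
            if ok:
                best = max(best, sum(e.weight for e in subset))
    return best


class TestGreedyPathMerge:
    def test_chain_of_consistent_edges(self):
        edges = [_edge("A", "B", 5), _edge("B", "C", 4)]
        paths = greedy_path_merge(["A", "B", "C"], edges, min_weight=3)
        assert len(paths) == 1
        assert [(e.contig_id, e.orientation) for e in paths[0].elements] == [
            ("A", "+"), ("B", "+"), ("C", "+"),
        ]

    def test_end_exclusivity(self):
        edges = [_edge("A", "B", 5), _edge("A", "C", 4)]  # both want A.R
        paths = greedy_path_merge(["A", "B", "C"], edges, min_weight=3)
        layouts = {tuple(e.contig_id for e in p.elements) for p in paths}
        assert ("A", "B") in layouts
        assert ("C",) in layouts

    def test_below_min_weight_discarded(self):
        paths = greedy_path_merge(["A", "B"], [_edge("A", "B", 2)], min_weight=3)
        assert len(paths) == 2

    def test_reverse_orientation_join(self):
        # joining A.R to B.R forces B to flip
        paths = greedy_path_merge(["A", "B"], [_edge("A", "B", 5, "R", "R")], min_weight=3)
        (p,) = paths
        assert [(e.contig_id, e.orientation) for e in p.elements] == [("A", "+"), ("B", "-")]

    def test_no_cycles(self):
        edges = [
            _edge("A", "B", 9), _edge("B", "C", 8, "R", "L"),
            _edge("A", "C", 7, "L", "R"),  # would close the circle
        ]
        paths = greedy_path_merge(["A", "B", "C"], edges, min_weight=1)
        assert len(paths) == 1
        assert len(paths[0].elements) == 3

    def test_partition_invariant(self):
        rng = np.random.default_rng(4)
        names = [f"c{i}" for i in range(12)]
        edges = [
            _edge(*sorted(rng.choice(names, 2, replace=False)), int(rng.integers(3, 9)),
                  rng.choice(["L", "R"]), rng.choice(["L", "R"]))
            for _ in range(20)
        ]
        paths = greedy_path_merge(names, edges, min_weight=3)
        placed = [e.contig_id for p in paths for e in p.elements]
        assert sorted(placed) == sorted(names)

    def test_equals_exhaustive_optimum_on_small_instances(self):
        # mate-pair-like instances: a true linear order whose adjacent
        # junctions carry the most links, plus weaker long-range skip edges
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(3, 7))
            names = [f"c{i}" for i in range(n)]
            order = list(rng.permutation(names))
            edges = []
            adj_w = rng.integers(10, 30, n - 1)
            for i in range(n - 1):
                edges.append(_edge(*sorted((order[i], order[i + 1])), int(adj_w[i]),
                                   gap=200.0, sd=float(rng.random())))
            for i in range(n - 2):
                if rng.random() < 0.5:
                    w = int(rng.integers(3, adj_w.min() + 1))
                    edges.append(_edge(*sorted((order[i], order[i + 2])), w,
                                       gap=2000.0, sd=float(rng.random())))
            # normalize ends to match the sorted pair ids
            fixed = []
            for e in edges:
                lo, hi = e.contig_a, e.contig_b
                ea, eb = ("R", "L") if order.index(lo) < order.index(hi) else ("L", "R")
                fixed.append(_edge(lo, hi, e.weight, ea, eb, e.gap_mean, e.gap_sd))
            paths = greedy_path_merge(names, fixed, min_weight=3)
            got = _accepted_weight(paths, fixed)
            assert got == _exhaustive_optimum(names, fixed)


class TestEmit:
    def test_lengths_and_gap(self):
        paths = greedy_path_merge(["A", "B"], [_edge("A", "B", 5, gap=50.0)], min_weight=3)
        seqs = {"A": "A" * 100, "B": "C" * 80}
        (rec,) = emit_scaffolds(paths, seqs)
        assert len(rec.seq) == 230
        assert len(rec.seq) - rec.seq.count("N") == 180

    def test_negative_gap_clamped_to_min_gap(self):
        paths = greedy_path_merge(["A", "B"], [_edge("A", "B", 5, gap=-200.0)], min_weight=3)
        (rec,) = emit_scaffolds(paths, {"A": "AA", "B": "CC"}, min_gap=10)
        assert rec.seq == "AA" + "N" * 10 + "CC"

    def test_reverse_complement_emission(self):
        paths = greedy_path_merge(["A", "B"], [_edge("A", "B", 5, "R", "R", gap=10.0)], min_weight=3)
        (rec,) = emit_scaffolds(paths, {"A": "AAAA", "B": "AACG"})
        # independent reverse complement of B
        rc = "AACG"[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert rec.seq == "AAAA" + "N" * 10 + rc

    def test_conservation_and_n50_never_drops(self):
        rng = np.random.default_rng(6)
        names = [f"c{i}" for i in range(10)]
        seqs = {n: "".join(rng.choice(list("ACGT"), int(rng.integers(50, 400)))) for n in names}
        edges = [
            _edge(*sorted((names[i], names[i + 1])), int(rng.integers(1, 10)))
            for i in range(9)
        ]
        paths = greedy_path_merge(names, edges, min_weight=3)
        records = emit_scaffolds(paths, seqs)
        ungapped = sum(len(r.seq) - r.seq.count("N") for r in records)
        assert ungapped == sum(len(s) for s in seqs.values())
        contig_n50, _ = nx_lx([len(s) for s in seqs.values()])
        scaf_n50 = assembly_stats(records).n50
        assert scaf_n50 >= contig_n50
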