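"""Greedy path-merging scaffolder.

Spanning mate links are bundled into weighted edges between contig ends;
edges are then processed greedily (weight descending, gap spread ascending,
lexicographic pair id) and accepted whenever both implicated contig ends are
free termini of distinct paths — the classic greedy path-merging strategy of
mate-pair scaffolders.  Accepted edges merge two paths; contigs never flip
relative to path mates already constraining them (whole paths may reverse).
Scaffold sequences are emitted with estimated gaps as N runs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from ._util import revcomp
from .io_formats import AssemblyRecord
from .mate_verify import MateLink


@dataclass(slots=True)
class BundledEdge:
    """Aggregated spanning-link evidence between two contig ends.

    ``end_a``/``end_b`` name the joined ends (L/R), normalized so that
    ``contig_a < contig_b`` lexicographically; together they encode one of
    the four relative-orientation classes.
    """

    contig_a: str
    contig_b: str
    end_a: str
    end_b: str
    weight: int
    gap_mean: float
    gap_sd: float

    @property
    def rel_orientation(self) -> str:
        return self.end_a + self.end_b  # RL/RR/LL/LR

    @property
    def key(self) -> Tuple[str, str, str, str]:
        return (self.contig_a, self.contig_b, self.end_a, self.end_b)


@dataclass(slots=True)
class PathElement:
    contig_id: str
    orientation: str  # + | -
    gap_after: Optional[float] = None  # absent on the last element


@dataclass(slots=True)
class ScaffoldPath:
    scaffold_id: str
    elements: List[PathElement]


def bundle_links(links: Iterable[MateLink]) -> Tuple[List[BundledEdge], int]:
    """Aggregate spanning links into bundled edges.

    Links are grouped by (normalized contig pair, orientation class);
    per group weight = link count, gap_mean / gap_sd = mean and sample SD of
    the per-link gap estimates (SD is +inf for singleton bundles — least
    trusted).  When several orientation classes contend for one contig pair
    only the max-weight class survives; the rest are returned as a
    discarded-conflict tally.
    """
    groups: Dict[Tuple[str, str, str, str], List[float]] = {}
    for link in links:
        if link.kind != "spanning":
            continue
        a, b = link.a.contig_id, link.b.contig_id
        ea, eb = link.end_a, link.end_b
        if b < a:
            a, b, ea, eb = b, a, eb, ea
        groups.setdefault((a, b, ea, eb), []).append(link.gap)

    by_pair: Dict[Tuple[str, str], List[BundledEdge]] = {}
    for (a, b, ea, eb), gaps in groups.items():
        n = len(gaps)
        mean = sum(gaps) / n
        if n > 1:
            sd = math.sqrt(sum((g - mean) ** 2 for g in gaps) / (n - 1))
        else:
            sd = math.inf
        by_pair.setdefault((a, b), []).append(
            BundledEdge(a, b, ea, eb, weight=n, gap_mean=mean, gap_sd=sd)
        )

    edges: List[BundledEdge] = []
    discarded = 0
    for pair in sorted(by_pair):
        classes = sorted(by_pair[pair], key=lambda e: (-e.weight, e.rel_orientation))
        edges.append(classes[0])
        discarded += sum(e.weight for e in classes[1:])
    return edges, discarded


class _Path:
    __slots__ = ("items", "gaps")

    def __init__(self, contig_id: str):
        self.items: List[Tuple[str, str]] = [(contig_id, "+")]
        self.gaps: List[float] = []  # gaps[i] sits between items[i] and items[i+1]

    def reverse(self) -> None:
        self.items = [(cid, "-" if o == "+" else "+") for cid, o in reversed(self.items)]
        self.gaps.reverse()


def _exposed_end(path: _Path, side: str) -> Tuple[str, str]:
    """(contig_id, free end) exposed at the given side of a path."""
    if side == "left":
        cid, orient = path.items[0]
        return cid, ("L" if orient == "+" else "R")
    cid, orient = path.items[-1]
    return cid, ("R" if orient == "+" else "L")


def greedy_path_merge(
    contig_ids: Iterable[str],
    edges: Sequence[BundledEdge],
    min_weight: int = 3,
) -> List[ScaffoldPath]:
    """Merge contigs into scaffold paths by greedy edge acceptance.

    Edges below ``min_weight`` are discarded; the rest are processed in
    deterministic order (weight desc, gap_sd asc, pair id) and accepted iff
    both implicated contig ends are currently free path termini of two
    different paths (no cycles, no interior attachment, no flip of an
    already-constrained contig).  Singleton paths are included in the output.
    """
    paths: Dict[str, _Path] = {cid: _Path(cid) for cid in contig_ids}

    def locate(cid: str, end: str) -> Optional[Tuple[_Path, str]]:
        path = paths[cid]
        for side in ("right", "left"):
            tid, free = _exposed_end(path, side)
            if tid == cid and free == end:
                return path, side
        return None

    order = sorted(edges, key=lambda e: (-e.weight, e.gap_sd, e.contig_a, e.contig_b, e.rel_orientation))
    for edge in order:
        if edge.weight < min_weight:
            continue
        pa = paths[edge.contig_a]
        pb = paths[edge.contig_b]
        if pa is pb:
            continue  # would close a cycle
        loc_a = locate(edge.contig_a, edge.end_a)
        loc_b = locate(edge.contig_b, edge.end_b)
        if loc_a is None or loc_b is None:
            continue  # an implicated end is not a free terminus
        path_a, side_a = loc_a
        path_b, side_b = loc_b
        if side_a == "left":
            path_a.reverse()
        if side_b == "right":
            path_b.reverse()
        # path_a now ends with contig_a exposing end_a on its right;
        # path_b starts with contig_b exposing end_b on its left
        path_a.gaps.append(edge.gap_mean)
        path_a.items.extend(path_b.items)
        path_a.gaps.extend(path_b.gaps)
        for cid, _ in path_b.items:
            paths[cid] = path_a

    out: List[ScaffoldPath] = []
    seen = set()
    serial = 0
    for cid in sorted(paths):
        path = paths[cid]
        if id(path) in seen:
            continue
        seen.add(id(path))
        serial += 1
        elements = [PathElement(c, o) for c, o in path.items]
        for i, gap in enumerate(path.gaps):
            elements[i].gap_after = gap
        out.append(ScaffoldPath(scaffold_id=f"scaffold_{serial:05d}", elements=elements))
    return out


def emit_scaffolds(
    paths: Sequence[ScaffoldPath],
    contig_seqs: Mapping[str, str],
    min_gap: int = 10,
) -> List[AssemblyRecord]:
    """Render scaffold paths as sequences with N gaps and AGP components.

    Contigs are concatenated in path order, reverse-complemented when '-',
    separated by N runs of ``max(round(gap_mean), min_gap)`` — negative
    estimated gaps (implied overlaps) are clamped rather than merged.
    """
    records: List[AssemblyRecord] = []
    for path in paths:
        parts: List[str] = []
        comps: List[tuple] = []
        for i, elem in enumerate(path.elements):
            seq = contig_seqs[elem.contig_id]
            parts.append(revcomp(seq) if elem.orientation == "-" else seq)
            comps.append(("W", elem.contig_id, len(seq), elem.orientation))
            if i < len(path.elements) - 1:
                gap = elem.gap_after if elem.gap_after is not None else min_gap
                gap_len = max(int(round(gap)), min_gap)
                parts.append("N" * gap_len)
                comps.append(("N", gap_len))
        records.append(AssemblyRecord(path.scaffold_id, "".join(parts), comps))
    return records
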