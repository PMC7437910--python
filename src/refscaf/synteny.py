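"""Synteny-block coalescing and gene-structure verification.

Colinear whole-genome alignment segments between two assemblies are chained
into syntenic blocks: segments shorter than ``min_seg`` (default 100 bp) are
discarded, the rest are grouped per (reference, query, strand) triple,
sorted along the reference, and consecutive segments are chained when the
gap on both genomes stays within ``max_join_gap`` and the query order is
monotone (reverse-monotone on the '-' strand).  Blocks below a span
threshold (1 Mb, or 500 kb for fragmented assemblies) can then be filtered
for plotting.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from ._util import union_length
from .io_formats import AlignmentSegment


@dataclass(slots=True)
class SyntenyBlock:
    ref_name: str
    ref_start: int
    ref_end: int
    qry_name: str
    qry_start: int
    qry_end: int
    strand: str
    segments: List[AlignmentSegment]

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(slots=True)
class GeneModel:
    """A gene's exons as ordered scaffold placements (transcript order)."""

    gene_id: str
    exons: List[Tuple[str, int, int, str]]  # (scaffold_id, start, end, strand)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: empty exon list")


def _trim_overlaps(segments: List[AlignmentSegment]) -> List[AlignmentSegment]:
    """Make ref intervals disjoint by splitting overlaps at their midpoint.

    Chaining requires disjoint segments; the symmetric midpoint split sheds
    the same number of reference columns from both neighbours.  Query
    coordinates shrink by the trimmed amount on the matching side ('-' strand
    segments map their ref prefix to the query suffix).
    """
    out: List[AlignmentSegment] = []
    for seg in segments:
        seg = AlignmentSegment(
            seg.ref_name, seg.ref_start, seg.ref_end,
            seg.qry_name, seg.qry_start, seg.qry_end, seg.strand,
        )
        while out and seg.ref_start < out[-1].ref_end:
            prev = out[-1]
            overlap = prev.ref_end - seg.ref_start
            cut_prev = overlap - overlap // 2
            cut_cur = overlap - cut_prev
            prev.ref_end -= cut_prev
            if prev.strand == "+":
                prev.qry_end -= cut_prev
            else:
                prev.qry_start += cut_prev
            seg.ref_start += cut_cur
            if seg.strand == "+":
                seg.qry_start += cut_cur
            else:
                seg.qry_end -= cut_cur
            if prev.ref_end - prev.ref_start < 1 or prev.qry_end - prev.qry_start < 1:
                out.pop()
                continue
            break
        if seg.ref_end - seg.ref_start >= 1 and seg.qry_end - seg.qry_start >= 1:
            out.append(seg)
    return out


def _chainable(a: AlignmentSegment, b: AlignmentSegment, max_join_gap: int) -> bool:
    ref_gap = b.ref_start - a.ref_end
    if ref_gap < 0 or ref_gap > max_join_gap:
        return False
    if a.strand == "+":
        qry_gap = b.qry_start - a.qry_end
    else:
        qry_gap = a.qry_start - b.qry_end
    return 0 <= qry_gap <= max_join_gap


def coalesce(
    segments: Iterable[AlignmentSegment],
    max_join_gap: int = 50_000,
    min_seg: int = 100,
) -> List[SyntenyBlock]:
    """Coalesce colinear alignment segments into syntenic blocks.

    Segments whose reference span is below ``min_seg`` are discarded.  Each
    maximal chain of consecutive, monotone segments (per reference/query/
    strand triple, gaps within ``max_join_gap`` on both genomes) becomes one
    block reported in reference coordinates.
    """
    groups: Dict[Tuple[str, str, str], List[AlignmentSegment]] = {}
    for seg in segments:
        if seg.ref_end - seg.ref_start < min_seg:
            continue
        groups.setdefault((seg.ref_name, seg.qry_name, seg.strand), []).append(seg)

    blocks: List[SyntenyBlock] = []
    for key in sorted(groups):
        segs = sorted(groups[key], key=lambda s: (s.ref_start, s.ref_end))
        segs = _trim_overlaps(segs)
        chain: List[AlignmentSegment] = []
        for seg in segs:
            if chain and _chainable(chain[-1], seg, max_join_gap):
                chain.append(seg)
            else:
                if chain:
                    blocks.append(_block_of(chain))
                chain = [seg]
        if chain:
            blocks.append(_block_of(chain))
    return blocks


def _block_of(chain: List[AlignmentSegment]) -> SyntenyBlock:
    return SyntenyBlock(
        ref_name=chain[0].ref_name,
        ref_start=chain[0].ref_start,
        ref_end=chain[-1].ref_end,
        qry_name=chain[0].qry_name,
        qry_start=min(s.qry_start for s in chain),
        qry_end=max(s.qry_end for s in chain),
        strand=chain[0].strand,
        segments=list(chain),
    )


def filter_blocks(blocks: Iterable[SyntenyBlock], min_block: int) -> List[SyntenyBlock]:
    """Keep blocks whose reference span reaches ``min_block``."""
    return [b for b in blocks if b.span >= min_block]


def verify_gene_structure(gene: GeneModel) -> str:
    """Check complete conservation of a gene's structure within one scaffold.

    ``verified`` iff all exons share one scaffold and one strand and their
    scaffold order matches transcript order (reversed on '-'); otherwise the
    first failing category in the order split -> strand_mixed -> disordered.
    """
    scaffolds = {e[0] for e in gene.exons}
    if len(scaffolds) > 1:
        return "split"
    strands = {e[3] for e in gene.exons}
    if len(strands) > 1:
        return "strand_mixed"
    starts = [e[1] for e in gene.exons]
    strand = gene.exons[0][3]
    ordered = starts if strand == "+" else starts[::-1]
    if all(a < b for a, b in zip(ordered, ordered[1:])):
        return "verified"
    return "disordered"


def reference_coverage(
    intervals: Iterable, ref_lengths: Mapping[str, int]
) -> Tuple[Dict[str, float], float]:
    """Covered fraction per reference sequence and their unweighted mean.

    Accepts anything with ``ref_name``/``ref_start``/``ref_end`` attributes
    (segments, placements) or plain ``(ref_name, start, end)`` triples.
    Sequences with no intervals count as 0; an interval on a sequence absent
    from ``ref_lengths`` is an error.
    """
    by_ref: Dict[str, List[Tuple[int, int]]] = {name: [] for name in ref_lengths}
    for iv in intervals:
        if isinstance(iv, tuple):
            name, s, e = iv
        else:
            name, s, e = iv.ref_name, iv.ref_start, iv.ref_end
        if name not in by_ref:
            raise ValueError(f"interval on unknown reference sequence {name!r}")
        by_ref[name].append((s, e))
    fractions = {
        name: union_length(ivs) / ref_lengths[name] for name, ivs in by_ref.items()
    }
    mean = sum(fractions.values()) / len(fractions) if fractions else float("nan")
    return fractions, mean
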