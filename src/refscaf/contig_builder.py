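"""Reference-anchored contig construction.

Reads mapped to the same reference locus are stitched into contigs: two
placements belong to the same cluster when their reference intervals share at
least ``min_overlap`` bases (default 50), clusters being the connected
components of that pairwise relation.  Each cluster yields one consensus
contig in the reference coordinate frame: per covered reference column the
majority projected symbol wins, a majority gap symbol deletes the column, and
insertions relative to the reference were already dropped at SAM ingestion.

Ties are broken by (1) highest summed base quality, (2) the reference base if
a reference window is supplied, then (3) ASCII order — the least surprising
rule for quality-aware majority calling.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._util import union_length
from .io_formats import GAP, Placement, QualityRead

_SYMBOLS = "ACGTN" + GAP
_GAP_IDX = _SYMBOLS.index(GAP)
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(_SYMBOLS):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


@dataclass(slots=True)
class Contig:
    """A stitched consensus sequence anchored to a reference locus.

    ``del_cols`` records the anchor-relative reference columns at which the
    consensus called a deletion (needed to lift read placements from
    reference to contig coordinates); ``len(seq) == anchor length -
    len(del_cols)``.
    """

    contig_id: str
    seq: str
    ref_name: str
    ref_start: int
    ref_end: int
    support: List[str]
    status: str = "unconfirmed"  # unconfirmed | confirmed | conflicted
    del_cols: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.seq)


def group_placements(
    placements: Sequence[Placement], min_overlap: int = 50
) -> List[List[Placement]]:
    """Cluster placements into connected components of the overlap relation.

    Two placements are chained iff their reference intervals share at least
    ``min_overlap`` bases.  Input may be unsorted (sorted internally) but must
    lie on a single reference sequence.  Every placement lands in exactly one
    cluster; clusters are returned in order of their leftmost start.
    """
    if not placements:
        return []
    refs = {p.ref_name for p in placements}
    if len(refs) > 1:
        raise ValueError(f"placements span multiple reference sequences: {sorted(refs)}")
    order = sorted(range(len(placements)), key=lambda i: (placements[i].ref_start, placements[i].ref_end))

    # Union-find over a left-to-right sweep.  For starts processed in order,
    # the best overlap a new placement can have with an existing component is
    # min(component max_end, end) - start, so tracking each active
    # component's max_end is sufficient; a component whose max_end falls
    # below start + min_overlap can never connect again and is retired.
    parent = list(range(len(placements)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    active: List[List[int]] = []  # [max_end, root]
    for idx in order:
        p = placements[idx]
        start, end = p.ref_start, p.ref_end
        keep: List[List[int]] = []
        merged_root = idx
        merged_max = end
        for comp in active:
            max_end, root = comp
            root = find(root)
            if max_end - start < min_overlap:
                continue  # retired: future starts are even larger
            if min(max_end, end) - start >= min_overlap:
                parent[find(merged_root)] = root
                merged_root = root
                merged_max = max(merged_max, max_end)
            else:
                comp[1] = root
                keep.append(comp)
        keep.append([merged_max, find(merged_root)])
        active = keep

    clusters: Dict[int, List[Placement]] = {}
    for idx in order:
        clusters.setdefault(find(idx), []).append(placements[idx])
    return sorted(clusters.values(), key=lambda c: c[0].ref_start)


def _pileup(cluster: Sequence[Placement], anchor_start: int, anchor_len: int):
    counts = np.zeros((anchor_len, len(_SYMBOLS)), dtype=np.int32)
    qsums = np.zeros((anchor_len, len(_SYMBOLS)), dtype=np.int64)
    for p in cluster:
        idx = _LUT[np.frombuffer(p.proj_bases.encode("ascii"), dtype=np.uint8)]
        if (idx < 0).any():
            raise ValueError(f"{p.read_id}: non-ACGTN symbol in projected bases")
        pos = np.arange(p.ref_start - anchor_start, p.ref_end - anchor_start)
        counts[pos, idx] += 1
        if p.proj_quals is not None:
            qsums[pos, idx] += np.frombuffer(p.proj_quals, dtype=np.uint8)
    return counts, qsums


def consensus(
    cluster: Sequence[Placement],
    reference_window: Optional[str] = None,
    contig_id: str = "contig",
) -> Contig:
    """Call the majority consensus of one cluster as a Contig.

    The anchor is ``[min ref_start, max ref_end)``; every internal column must
    be covered by at least one read (guaranteed for clusters produced by
    :func:`group_placements` with a positive overlap threshold).
    ``reference_window`` — the reference bases across the anchor — only
    participates in tie-breaking.
    """
    if not cluster:
        raise ValueError("cannot build a consensus from an empty cluster")
    anchor_start = min(p.ref_start for p in cluster)
    anchor_end = max(p.ref_end for p in cluster)
    anchor_len = anchor_end - anchor_start
    counts, qsums = _pileup(cluster, anchor_start, anchor_len)
    coverage = counts.sum(axis=1)
    if (coverage == 0).any():
        col = int(np.argmax(coverage == 0))
        raise ValueError(f"internal zero-coverage column at anchor offset {col}")

    # Composite score: count dominates, then summed quality, then the
    # reference base, then ASCII order.  Quality sums are integers, so a
    # spacing of 8 per unit keeps the lower-priority bonuses from ever
    # crossing a quality step.
    score = counts.astype(np.float64) * 1e12 + qsums.astype(np.float64) * 8.0
    if reference_window is not None:
        if len(reference_window) != anchor_len:
            raise ValueError("reference_window must span the anchor exactly")
        ref_idx = _LUT[np.frombuffer(reference_window.upper().encode("ascii"), dtype=np.uint8)]
        valid = ref_idx >= 0
        score[np.arange(anchor_len)[valid], ref_idx[valid]] += 4.0
    # ASCII order among "ACGTN-": '-' < uppercase letters
    ascii_rank = np.argsort(np.argsort([ord(c) for c in _SYMBOLS]))
    score += (len(_SYMBOLS) - ascii_rank) * 0.5

    winners = score.argmax(axis=1)
    keep = winners != _GAP_IDX
    seq = "".join(_SYMBOLS[i] for i in winners[keep])
    del_cols = np.nonzero(~keep)[0]
    return Contig(
        contig_id=contig_id,
        seq=seq,
        ref_name=cluster[0].ref_name,
        ref_start=anchor_start,
        ref_end=anchor_end,
        support=[p.read_id for p in cluster],
        del_cols=del_cols,
    )


def build_contigs(
    placements: Sequence[Placement],
    min_overlap: int = 50,
    ref_lengths: Optional[Mapping[str, int]] = None,
    reference: Optional[Mapping[str, str]] = None,
    min_support: int = 1,
) -> Tuple[List[Contig], Dict[str, Dict[str, float]]]:
    """Stitch placements (possibly on several references) into contigs.

    Returns the contigs plus a per-reference coverage summary: the fraction
    of each reference sequence covered by >=1 placement and by >=1 contig
    (requires ``ref_lengths``; fractions are NaN otherwise).  Clusters with
    fewer than ``min_support`` reads are dropped.
    """
    by_ref: Dict[str, List[Placement]] = {}
    for p in placements:
        by_ref.setdefault(p.ref_name, []).append(p)

    contigs: List[Contig] = []
    summary: Dict[str, Dict[str, float]] = {}
    serial = 0
    for ref_name in sorted(by_ref):
        plc = by_ref[ref_name]
        clusters = group_placements(plc, min_overlap=min_overlap)
        ref_seq = reference.get(ref_name) if reference is not None else None
        kept: List[Contig] = []
        for cluster in clusters:
            if len(cluster) < min_support:
                continue
            serial += 1
            window = None
            if ref_seq is not None:
                s = min(p.ref_start for p in cluster)
                e = max(p.ref_end for p in cluster)
                window = ref_seq[s:e]
            kept.append(consensus(cluster, reference_window=window, contig_id=f"contig_{serial:06d}"))
        contigs.extend(kept)
        ref_len = float(ref_lengths[ref_name]) if ref_lengths and ref_name in ref_lengths else float("nan")
        summary[ref_name] = {
            "read_covered_bp": union_length((p.ref_start, p.ref_end) for p in plc),
            "contig_covered_bp": union_length((c.ref_start, c.ref_end) for c in kept),
        }
        summary[ref_name]["read_fraction"] = summary[ref_name]["read_covered_bp"] / ref_len
        summary[ref_name]["contig_fraction"] = summary[ref_name]["contig_covered_bp"] / ref_len
    return contigs, summary


def collect_unmapped(
    all_reads: Iterable[QualityRead], unmapped_ids: Iterable[str]
) -> List[QualityRead]:
    """Select exactly the unmapped reads, order-stable, for external assembly.

    Ids not present in ``all_reads`` trigger a warning naming the count.
    """
    wanted = set(unmapped_ids)
    out = [r for r in all_reads if r.read_id in wanted]
    missing = len(wanted) - len({r.read_id for r in out})
    if missing:
        warnings.warn(f"{missing} unmapped read id(s) not found in the read set")
    return out
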