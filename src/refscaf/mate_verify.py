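"""Mate-pair link classification and contig confirmation.

Mate pairs carry long-range information: both mates landing on one contig
confirm it, mates landing near the facing ends of two contigs support a
join, and any other geometry (a mate buried far from the gap-facing end, or
an orientation the library cannot produce) signals a potential misassembly.
A contig is confirmed when at least ``min_support`` pairs map entirely
within it and no conflicting pair touches it — a link joining two contigs in
a non-suffix-prefix manner disqualifies both.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .contig_builder import Contig
from .io_formats import Placement


@dataclass(frozen=True, slots=True)
class LibrarySpec:
    """Insert-size model of a sequencing library.

    ``orientation`` is the expected relative orientation of the two mates:
    ``ff`` (same strand, mate-pair chemistry such as SOLiD) or ``fr``
    (inward-facing, short-insert paired-end chemistry).
    """

    name: str
    insert_mean: float
    insert_sd: float
    orientation: str = "ff"

    def __post_init__(self) -> None:
        if self.insert_mean <= 0 or self.insert_sd < 0:
            raise ValueError("insert_mean must be > 0 and insert_sd >= 0")
        if self.orientation not in ("ff", "fr"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def default_end_window(self) -> float:
        """Beyond insert_mean + 3*insert_sd an implied gap is implausible."""
        return self.insert_mean + 3.0 * self.insert_sd


@dataclass(slots=True)
class ContigPlacement:
    """A read placement lifted into contig coordinates."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    contig_len: int
    mate_role: str = "fragment"


@dataclass(slots=True)
class MateLink:
    """A classified mate pair: intra, spanning, or conflicting."""

    pair_id: str
    a: ContigPlacement
    b: ContigPlacement
    library: LibrarySpec
    kind: str
    end_a: Optional[str] = None  # gap-facing end of a's contig: L or R
    end_b: Optional[str] = None
    gap: Optional[float] = None  # implied gap (negative = overlap)


def lift_to_contigs(
    placements: Iterable[Placement], contigs: Sequence[Contig]
) -> Tuple[List[ContigPlacement], int]:
    """Lift reference placements into contig coordinates.

    The contig offset is the reference offset minus the number of consensus
    deletion columns preceding it.  A placement intersecting no contig is
    dropped (tallied); one straddling two contigs goes to the larger
    intersection, ties to the lexicographically smaller contig id.
    """
    by_ref: Dict[str, List[Contig]] = {}
    for c in contigs:
        by_ref.setdefault(c.ref_name, []).append(c)
    starts: Dict[str, np.ndarray] = {}
    max_ends: Dict[str, np.ndarray] = {}  # prefix max of anchor ends
    for ref, cs in by_ref.items():
        cs.sort(key=lambda c: c.ref_start)
        starts[ref] = np.array([c.ref_start for c in cs])
        max_ends[ref] = np.maximum.accumulate(np.array([c.ref_end for c in cs]))

    def mate_role(read_id: str) -> str:
        if read_id.endswith("/1"):
            return "mate_first"
        if read_id.endswith("/2"):
            return "mate_second"
        return "fragment"

    lifted: List[ContigPlacement] = []
    dropped = 0
    for p in placements:
        cs = by_ref.get(p.ref_name)
        if not cs:
            dropped += 1
            continue
        i = int(np.searchsorted(starts[p.ref_name], p.ref_start, side="right")) - 1
        best = None
        best_key = None
        # anchors may overlap or nest, so ends are not monotone: scan left
        # guided by the prefix max of anchor ends, right by anchor starts
        candidates = []
        me = max_ends[p.ref_name]
        j = i
        while j >= 0 and me[j] > p.ref_start:
            if cs[j].ref_end > p.ref_start:
                candidates.append(cs[j])
            j -= 1
        j = i + 1
        while j < len(cs) and cs[j].ref_start < p.ref_end:
            candidates.append(cs[j])
            j += 1
        for c in candidates:
            inter = min(p.ref_end, c.ref_end) - max(p.ref_start, c.ref_start)
            if inter > 0:
                key = (-inter, c.contig_id)
                if best is None or key < best_key:
                    best, best_key = c, key
        if best is None:
            dropped += 1
            continue
        c = best
        off_s = p.ref_start - c.ref_start
        off_e = p.ref_end - c.ref_start
        start = off_s - int(np.searchsorted(c.del_cols, off_s, side="left"))
        end = off_e - int(np.searchsorted(c.del_cols, off_e, side="left"))
        start = max(0, min(start, len(c.seq)))
        end = max(start + 1, min(end, len(c.seq)))
        lifted.append(
            ContigPlacement(
                read_id=p.read_id,
                contig_id=c.contig_id,
                start=start,
                end=end,
                strand=p.strand,
                contig_len=len(c.seq),
                mate_role=mate_role(p.read_id),
            )
        )
    return lifted, dropped


def _points_right(cp: ContigPlacement, library: LibrarySpec) -> bool:
    """Whether the mate 'points' toward increasing contig coordinates.

    In ``fr`` both mates read toward each other, so each points along its own
    strand.  In ``ff`` both reads sit on the same strand of the fragment: the
    first mate points along its strand toward the second, and the second
    points back against its strand.
    """
    if library.orientation == "fr" or cp.mate_role != "mate_second":
        return cp.strand == "+"
    return cp.strand == "-"


def _gap_distance(cp: ContigPlacement, library: LibrarySpec) -> Tuple[float, str]:
    """Distance from the mate's outer coordinate to its gap-facing end."""
    if _points_right(cp, library):
        return float(cp.contig_len - cp.start), "R"
    return float(cp.end), "L"


def estimate_gap(a: ContigPlacement, b: ContigPlacement, library: LibrarySpec) -> float:
    """Implied gap between two contigs: insert_mean - d_a - d_b.

    ``d_x`` is the distance from each mate's outer coordinate to the
    gap-facing end of its contig; a negative result implies contig overlap.
    """
    d_a, _ = _gap_distance(a, library)
    d_b, _ = _gap_distance(b, library)
    return library.insert_mean - d_a - d_b


def classify_link(
    a: ContigPlacement,
    b: ContigPlacement,
    library: LibrarySpec,
    end_window: Optional[float] = None,
) -> MateLink:
    """Classify one lifted mate pair.

    Same contig -> ``intra``.  Different contigs where each mate lies within
    ``end_window`` of the contig end facing the implied gap -> ``spanning``
    (with the joined ends and a gap estimate attached).  Anything else ->
    ``conflicting``.
    """
    if library is None:
        raise ValueError("a library spec is required to classify a link")
    pair_id = a.read_id.rsplit("/", 1)[0]
    if a.contig_id == b.contig_id:
        return MateLink(pair_id, a, b, library, "intra")
    w = library.default_end_window if end_window is None else end_window
    d_a, end_a = _gap_distance(a, library)
    d_b, end_b = _gap_distance(b, library)
    if d_a <= w and d_b <= w:
        return MateLink(
            pair_id, a, b, library, "spanning",
            end_a=end_a, end_b=end_b,
            gap=library.insert_mean - d_a - d_b,
        )
    return MateLink(pair_id, a, b, library, "conflicting")


def pair_links(
    lifted: Iterable[ContigPlacement],
    library_of: Callable[[str], LibrarySpec],
    end_window: Optional[float] = None,
    end_window_sds: Optional[float] = None,
) -> List[MateLink]:
    """Group lifted placements into pairs and classify each complete pair.

    ``library_of`` maps a read id to its LibrarySpec.  Pairs missing a mate
    (unmapped or discarded partner) produce no link.  ``end_window_sds``
    sets the window per library as ``insert_mean + k * insert_sd`` — use
    the number of SDs covering the insert distribution's support (e.g. 4
    for a generator that truncates inserts at +/-4 SD), otherwise genuine
    long-insert pairs misclassify as conflicting.
    """
    halves: Dict[str, Dict[str, ContigPlacement]] = {}
    for cp in lifted:
        if cp.mate_role == "fragment":
            continue
        stem = cp.read_id.rsplit("/", 1)[0]
        halves.setdefault(stem, {})[cp.mate_role] = cp
    links: List[MateLink] = []
    for stem in sorted(halves):
        pair = halves[stem]
        if "mate_first" in pair and "mate_second" in pair:
            lib = library_of(stem)
            window = end_window
            if window is None and end_window_sds is not None:
                window = lib.insert_mean + end_window_sds * lib.insert_sd
            links.append(
                classify_link(
                    pair["mate_first"], pair["mate_second"], lib, end_window=window,
                )
            )
    return links


def confirm_contigs(
    contigs: Sequence[Contig],
    links: Iterable[MateLink],
    min_support: int = 3,
    max_conflicts: int = 0,
) -> List[Contig]:
    """Set each contig's confirmation status from classified links.

    ``confirmed``: >= ``min_support`` intra links and no more than
    ``max_conflicts`` conflicting links touch it.  ``conflicted``: more than
    ``max_conflicts`` conflicting links touch it.  Otherwise ``unconfirmed``.
    Statuses are set in place and the contigs returned.
    """
    intra: Dict[str, int] = {}
    conflicts: Dict[str, int] = {}
    for link in links:
        if link.kind == "intra":
            intra[link.a.contig_id] = intra.get(link.a.contig_id, 0) + 1
        elif link.kind == "conflicting":
            for cid in (link.a.contig_id, link.b.contig_id):
                conflicts[cid] = conflicts.get(cid, 0) + 1
    for c in contigs:
        if conflicts.get(c.contig_id, 0) > max_conflicts:
            c.status = "conflicted"
        elif intra.get(c.contig_id, 0) >= min_support:
            c.status = "confirmed"
        else:
            c.status = "unconfirmed"
    return list(contigs)
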