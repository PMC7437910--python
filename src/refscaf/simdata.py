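"""Deterministic synthetic data for end-to-end pipeline testing.

The generator emulates the study design the toolkit targets: a donor genome
is sequenced as short fragment reads (75 bp) plus two long-insert mate-pair
libraries (1 kb and 3 kb, 60 bp reads), and the reads are anchored to a
*diverged* reference genome (the donor with substitutions and short indels
applied, standing in for a related species).  Alignments are derived from
the known truth rather than an external mapper, so every pipeline stage is
testable hermetically; base-calling errors and a linearly decaying quality
profile with per-cycle noise exercise trimming and consensus calling.

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` stream, so outputs are byte-identical across
runs and platforms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import edlib
import numpy as np

from ._util import merge_intervals, revcomp, union_length
from .contig_builder import Contig
from .io_formats import QualityRead
from .mate_verify import LibrarySpec
from .scaffolder import ScaffoldPath

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_libraries() -> Tuple[LibrarySpec, ...]:
    return (
        LibrarySpec("m1k", 1000.0, 100.0, "ff"),
        LibrarySpec("m3k", 3000.0, 300.0, "ff"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    ``quality_*`` describe a linearly decreasing mean-quality profile: the
    mean starts at ``quality_start`` and crosses the Q15 trimming floor at
    cycle ``quality_cross_frac * read_len``, with Gaussian per-base noise.
    The default crossing sits past the read end, giving mild 3' tail
    trimming that leaves reads longer than the 50 bp stitching overlap — a
    read trimmed below the overlap threshold can never chain and would
    surface as a nested single-read contig.  Lowering the crossing toward
    0.7 reproduces heavy-trimming regimes for studying the trimmer itself.
    """

    seed: int
    genome_len: int = 2_000_000
    divergence: float = 0.02
    indel_rate: float = 0.001
    repeat_fraction: float = 0.0
    # hypervariable patches: short donor regions so diverged from the
    # reference that reads overlapping them substantially cannot be mapped.
    # They are what breaks a reference-guided assembly into contigs and what
    # feeds the unmapped-read collection for external de novo assembly.
    patch_rate: float = 5e-5  # expected patches per donor bp
    patch_len_range: Tuple[int, int] = (150, 450)
    patch_divergence: float = 0.25
    patch_min_sep: int = 5_000
    unmappable_overlap_frac: float = 0.3
    read_len_fragment: int = 75
    read_len_mate: int = 60
    coverage_fragment: float = 30.0
    coverage_mate: float = 10.0  # per mate library
    libraries: Tuple[LibrarySpec, ...] = field(default_factory=_default_libraries)
    base_error_rate: float = 0.01
    quality_start: float = 30.0
    quality_cross_frac: float = 1.6
    quality_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for rate in (self.divergence, self.indel_rate, self.repeat_fraction, self.base_error_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if self.genome_len < 10_000:
            raise ValueError("genome_len must be >= 10 kb")
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic call")


@dataclass
class SimGenomes:
    """Donor/reference pair with the full edit truth.

    ``donor2ref[i]`` is the reference column of donor base ``i`` (-1 when the
    base was deleted from the reference); ``hot_sites`` lists donor positions
    touched by an indel edit, used to fast-path reads that align gaplessly.
    """

    donor: str
    reference: str
    sub_pos: np.ndarray
    indels: List[Tuple[str, int, int]]  # (kind, donor_pos, length)
    donor2ref: np.ndarray
    hot_sites: np.ndarray
    patches: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    patch_sub_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def edit_table(self) -> str:
        lines = ["kind\tdonor_pos\tlength"]
        events = [("sub", int(p), 1) for p in self.sub_pos] + [
            (k, p, l) for k, p, l in self.indels
        ]
        for kind, pos, length in sorted(events, key=lambda e: e[1]):
            lines.append(f"{kind}\t{pos}\t{length}")
        return "\n".join(lines) + "\n"


def simulate_genomes(config: SimConfig) -> SimGenomes:
    """Generate a donor genome and a diverged reference with edit truth.

    The reference is derived from the donor by substitutions at
    ``divergence`` and 1-3 bp insertions/deletions at ``indel_rate``
    (sites closer than 5 bp to a previous indel are skipped so edits never
    overlap).  ``repeat_fraction`` of the donor is built from dispersed
    copies of a seeded 500 bp motif.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_len
    donor_idx = rng.integers(0, 4, L, dtype=np.int8)
    if config.repeat_fraction > 0:
        motif_len = min(500, L // 20)
        motif = rng.integers(0, 4, motif_len, dtype=np.int8)
        n_copies = int(L * config.repeat_fraction / motif_len)
        for pos in rng.integers(0, L - motif_len + 1, n_copies):
            donor_idx[pos:pos + motif_len] = motif

    sub_mask = rng.random(L) < config.divergence
    sub_pos = np.nonzero(sub_mask)[0]
    ref_idx = donor_idx.copy()
    ref_idx[sub_pos] = (ref_idx[sub_pos] + rng.integers(1, 4, sub_pos.size)) % 4

    # hypervariable patches: heavily substituted in the reference, and
    # flagged so the truth aligner refuses reads that overlap them enough
    patches: List[Tuple[int, int]] = []
    n_patch = int(round(config.patch_rate * L))
    if n_patch:
        lo, hi = config.patch_len_range
        cand = np.sort(rng.integers(0, L - hi, 4 * n_patch))
        lens = rng.integers(lo, hi + 1, cand.size)
        last_end = -config.patch_min_sep
        for s, pl in zip(cand, lens):
            if len(patches) >= n_patch:
                break
            if int(s) - last_end < config.patch_min_sep:
                continue
            patches.append((int(s), int(s) + int(pl)))
            last_end = int(s) + int(pl)
    patch_arr = np.array(patches, dtype=np.int64).reshape(-1, 2)
    patch_subs: List[np.ndarray] = []
    for s, e in patches:
        hit = s + np.nonzero(rng.random(e - s) < config.patch_divergence)[0]
        ref_idx[hit] = (ref_idx[hit] + rng.integers(1, 4, hit.size)) % 4
        patch_subs.append(hit)
    patch_sub_pos = (
        np.concatenate(patch_subs) if patch_subs else np.empty(0, dtype=np.int64)
    )

    raw_sites = np.nonzero(rng.random(L) < config.indel_rate)[0]
    indels: List[Tuple[str, int, int]] = []
    last = -10
    for pos in raw_sites:
        pos = int(pos)
        if pos - last < 5 or pos < 1 or pos > L - 5:
            continue
        kind = "ins" if rng.random() < 0.5 else "del"
        length = int(rng.integers(1, 4))
        indels.append((kind, pos, length))
        last = pos + (length if kind == "del" else 0)

    donor2ref = np.arange(L, dtype=np.int64)
    pieces: List[np.ndarray] = []
    hot: List[int] = []
    prev = 0
    shift = 0
    for kind, pos, length in indels:
        pieces.append(ref_idx[prev:pos])
        donor2ref[prev:pos] += shift
        if kind == "ins":
            pieces.append(rng.integers(0, 4, length, dtype=np.int8))
            shift += length
            hot.append(pos)
            prev = pos
        else:
            donor2ref[pos:pos + length] = -1
            shift -= length
            hot.extend(range(pos, pos + length))
            prev = pos + length
    pieces.append(ref_idx[prev:])
    donor2ref[prev:] += shift

    donor = _BASES[donor_idx].tobytes().decode("ascii")
    reference = _BASES[np.concatenate(pieces)].tobytes().decode("ascii")
    return SimGenomes(
        donor=donor,
        reference=reference,
        sub_pos=sub_pos,
        indels=indels,
        donor2ref=donor2ref,
        hot_sites=np.array(sorted(hot), dtype=np.int64),
        patches=patch_arr,
        patch_sub_pos=patch_sub_pos,
    )


@dataclass
class ReadTruth:
    start: int  # donor coordinates of the full-length read
    end: int
    strand: str


@dataclass
class SimReadSet:
    reads: List[QualityRead]
    truth: Dict[str, ReadTruth]
    libraries: Dict[str, LibrarySpec]

    def library_of(self, read_stem: str) -> LibrarySpec:
        return self.libraries[read_stem.split("-", 1)[0]]


def _quality_matrix(rng, n: int, read_len: int, config: SimConfig) -> np.ndarray:
    cycles = np.arange(read_len)
    cross = config.quality_cross_frac * read_len
    mean = config.quality_start + (15.0 - config.quality_start) * (cycles / cross)
    q = np.rint(mean[None, :] + rng.normal(0.0, config.quality_noise_sd, (n, read_len)))
    return np.clip(q, 2, 41).astype(np.uint8)


def _read_matrix(rng, donor_idx: np.ndarray, starts: np.ndarray, minus: np.ndarray,
                 read_len: int, error_rate: float) -> np.ndarray:
    mat = donor_idx[starts[:, None] + np.arange(read_len)]
    if minus.any():
        mat[minus] = (3 - mat[minus])[:, ::-1]
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        mat = np.where(err, (mat + rng.integers(1, 4, mat.shape)) % 4, mat)
    return mat


def _emit_reads(ids: Iterable[str], mat: np.ndarray, quals: np.ndarray,
                run_label: str, roles: Sequence[str]) -> List[QualityRead]:
    ascii_mat = _BASES[mat]
    out: List[QualityRead] = []
    for i, rid in enumerate(ids):
        out.append(
            QualityRead(
                read_id=rid,
                bases=ascii_mat[i].tobytes().decode("ascii"),
                quals=quals[i].tobytes(),
                run_label=run_label,
                mate_role=roles[i] if len(roles) > 1 else roles[0],
            )
        )
    return out


def simulate_reads(genomes: SimGenomes, config: SimConfig) -> SimReadSet:
    """Simulate fragment and mate-pair read sets with truth positions.

    Start positions are uniform over the donor; mate pairs are separated per
    library by a normal insert truncated at +/-4 SD, with ``ff`` libraries
    placing both mates on the fragment strand (the upstream mate is
    ``mate_first``).  Per-base errors occur at ``base_error_rate``;
    qualities follow the decaying profile.  FASTQ-ready reads are returned
    in sequencing orientation alongside a truth table of full-length donor
    intervals.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    L = config.genome_len
    # decode donor bases ACGT -> 0..3
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    donor_idx = lut[np.frombuffer(genomes.donor.encode("ascii"), dtype=np.uint8)]

    reads: List[QualityRead] = []
    truth: Dict[str, ReadTruth] = {}

    # fragment library
    flen = config.read_len_fragment
    n_frag = int(round(config.coverage_fragment * L / flen)) if config.coverage_fragment > 0 else 0
    if n_frag:
        starts = rng.integers(0, L - flen + 1, n_frag)
        minus = rng.random(n_frag) < 0.5
        mat = _read_matrix(rng, donor_idx, starts, minus, flen, config.base_error_rate)
        quals = _quality_matrix(rng, n_frag, flen, config)
        ids = [f"frag-{i:07d}" for i in range(n_frag)]
        reads.extend(_emit_reads(ids, mat, quals, "frag", ["fragment"]))
        for i in range(n_frag):
            truth[ids[i]] = ReadTruth(int(starts[i]), int(starts[i]) + flen,
                                      "-" if minus[i] else "+")

    # mate-pair libraries
    mlen = config.read_len_mate
    for lib in config.libraries:
        n_pairs = int(round(config.coverage_mate * L / mlen)) // 2 if config.coverage_mate > 0 else 0
        if not n_pairs:
            continue
        raw = rng.normal(lib.insert_mean, lib.insert_sd, n_pairs)
        inserts = np.clip(np.rint(raw), lib.insert_mean - 4 * lib.insert_sd,
                          lib.insert_mean + 4 * lib.insert_sd).astype(np.int64)
        inserts = np.maximum(inserts, mlen)
        p = np.floor(rng.random(n_pairs) * (L - inserts + 1)).astype(np.int64)
        minus = rng.random(n_pairs) < 0.5
        up_start = p                      # upstream interval
        dn_start = p + inserts - mlen     # downstream interval
        # ff: mate_first sits at the fragment's 5' end — upstream on '+',
        # downstream on '-'; both mates map to the fragment strand
        first_start = np.where(minus, dn_start, up_start)
        second_start = np.where(minus, up_start, dn_start)
        mat1 = _read_matrix(rng, donor_idx, first_start, minus, mlen, config.base_error_rate)
        mat2 = _read_matrix(rng, donor_idx, second_start, minus, mlen, config.base_error_rate)
        q1 = _quality_matrix(rng, n_pairs, mlen, config)
        q2 = _quality_matrix(rng, n_pairs, mlen, config)
        ids1 = [f"{lib.name}-{i:07d}/1" for i in range(n_pairs)]
        ids2 = [f"{lib.name}-{i:07d}/2" for i in range(n_pairs)]
        reads.extend(_emit_reads(ids1, mat1, q1, lib.name, ["mate_first"]))
        reads.extend(_emit_reads(ids2, mat2, q2, lib.name, ["mate_second"]))
        for i in range(n_pairs):
            strand = "-" if minus[i] else "+"
            truth[ids1[i]] = ReadTruth(int(first_start[i]), int(first_start[i]) + mlen, strand)
            truth[ids2[i]] = ReadTruth(int(second_start[i]), int(second_start[i]) + mlen, strand)

    libraries = {lib.name: lib for lib in config.libraries}
    libraries["frag"] = LibrarySpec("frag", max(2 * flen, 4), 1.0, "fr")
    return SimReadSet(reads=reads, truth=truth, libraries=libraries)


# ---------------------------------------------------------------------------
# truth-derived SAM

def _cigar_for(genomes: SimGenomes, s: int, e: int) -> Optional[Tuple[int, str]]:
    """CIGAR and reference start for the donor interval [s, e).

    Donor bases deleted from the reference become I (S at the read edges);
    reference-only insertions inside the interval become D.  Returns None
    when no base of the interval survives in the reference.
    """
    d2r = genomes.donor2ref
    lo = int(np.searchsorted(genomes.hot_sites, s, side="left"))
    hi = int(np.searchsorted(genomes.hot_sites, e, side="left"))
    if lo == hi and d2r[s] >= 0:
        return int(d2r[s]), f"{e - s}M"  # gapless fast path
    cols = d2r[s:e]
    mapped = np.nonzero(cols >= 0)[0]
    if mapped.size == 0:
        return None
    first, last = int(mapped[0]), int(mapped[-1])
    ops: List[List] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1][1] += n
        else:
            ops.append([op, n])

    push("S", first)
    prev_col = None
    for i in range(first, last + 1):
        col = int(cols[i])
        if col < 0:
            push("I", 1)  # donor base absent from the reference
        else:
            if prev_col is not None and col > prev_col + 1:
                push("D", col - prev_col - 1)
            push("M", 1)
            prev_col = col
    push("S", e - s - 1 - last)
    cigar = "".join(f"{n}{op}" for op, n in ops)
    return int(cols[first]), cigar


def write_truth_sam(
    reads: Iterable[QualityRead],
    genomes: SimGenomes,
    readset: SimReadSet,
    path: Union[str, Path],
    ref_name: str = "ref",
    unmappable_overlap_frac: float = 0.3,
) -> int:
    """Write coordinate-sorted SAM derived from the simulation truth.

    Accepts possibly-trimmed reads: a trimmed read is a sequencing-order
    prefix, which on the '-' strand corresponds to a suffix of the donor
    interval.  SEQ/QUAL are emitted in reference orientation per the SAM
    convention.  Reads are written as unmapped (flag 4) when their interval
    retains no reference column or when at least
    ``unmappable_overlap_frac`` of the read lies in a hypervariable patch —
    a mapper confronted with ~25% local divergence would not place them.
    Returns the record count.
    """
    p_starts = genomes.patches[:, 0]
    p_ends = genomes.patches[:, 1]

    def patch_overlap(s: int, e: int) -> int:
        lo = int(np.searchsorted(p_ends, s, side="right"))
        hi = int(np.searchsorted(p_starts, e, side="left"))
        return sum(
            min(e, int(p_ends[k])) - max(s, int(p_starts[k]))
            for k in range(lo, hi)
        )

    rows: List[Tuple[int, str]] = []
    for read in reads:
        t = readset.truth[read.read_id]
        n = len(read)
        if t.strand == "+":
            s, e = t.start, t.start + n
            seq, qual = read.bases, read.quals
        else:
            s, e = t.end - n, t.end
            seq, qual = revcomp(read.bases), read.quals[::-1]
        qual_str = bytes(q + 33 for q in qual).decode("ascii")
        flag = 16 if t.strand == "-" else 0
        if read.read_id.endswith("/1"):
            flag |= 0x1 | 0x40
        elif read.read_id.endswith("/2"):
            flag |= 0x1 | 0x80
        placed = _cigar_for(genomes, s, e)
        if p_starts.size and patch_overlap(s, e) >= unmappable_overlap_frac * n:
            placed = None
        if placed is None:
            rows.append((-1, f"{read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual_str}"))
            continue
        ref_start, cigar = placed
        rows.append(
            (ref_start,
             f"{read.read_id}\t{flag}\t{ref_name}\t{ref_start + 1}\t60\t{cigar}"
             f"\t*\t0\t0\t{seq}\t{qual_str}")
        )
    rows.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{len(genomes.reference)}\n")
        for _, line in rows:
            fh.write(line + "\n")
    return len(rows)


@dataclass
class RecoveryReport:
    """How faithfully an assembly recovers the simulated donor."""

    donor_coverage_pct: float
    consensus_identity_pct: float
    adjacency_accuracy_pct: float
    n_true_adjacent_pairs: int
    n_correct_joins: int


def _anchor_to_donor(genomes: SimGenomes, ref_start: int, ref_end: int) -> Optional[Tuple[int, int]]:
    r2d = _ref2donor(genomes)
    window = r2d[ref_start:ref_end]
    mapped = window[window >= 0]
    if mapped.size == 0:
        return None
    return int(mapped.min()), int(mapped.max()) + 1


_R2D_CACHE: Dict[int, np.ndarray] = {}


def _ref2donor(genomes: SimGenomes) -> np.ndarray:
    key = id(genomes)
    if key not in _R2D_CACHE:
        r2d = np.full(len(genomes.reference), -1, dtype=np.int64)
        mapped = genomes.donor2ref >= 0
        r2d[genomes.donor2ref[mapped]] = np.nonzero(mapped)[0]
        _R2D_CACHE.clear()  # keep at most one genome's map around
        _R2D_CACHE[key] = r2d
    return _R2D_CACHE[key]


def truth_evaluate(
    contigs: Sequence[Contig],
    paths: Sequence[ScaffoldPath],
    genomes: SimGenomes,
) -> RecoveryReport:
    """Score an assembly against the simulation truth.

    Donor coverage: fraction of the donor covered by contig anchors lifted
    through the edit map.  Consensus identity: edit-distance identity of
    each contig against its anchored donor window (edlib, length-weighted).
    Adjacency accuracy: fraction of truly neighbouring contig pairs joined
    next to each other in a scaffold path with consistent orientation.
    True neighbours are consecutive anchors of the *backbone* tiling —
    contigs whose anchor is contained inside another contig's anchor (e.g.
    a single over-trimmed read nested in a long contig) have no defined
    left/right neighbour and are excluded from the adjacency truth.  An
    empty assembly scores 0/0/0; a single-contig truth has no pairs and
    scores adjacency 100.
    """
    if not contigs:
        return RecoveryReport(0.0, 0.0, 0.0, 0, 0)
    donor_ivs = []
    dist_sum = 0
    col_sum = 0
    anchored: List[Tuple[int, int, Contig]] = []
    for c in contigs:
        iv = _anchor_to_donor(genomes, c.ref_start, c.ref_end)
        if iv is None:
            continue
        donor_ivs.append(iv)
        anchored.append((iv[0], iv[1], c))
        window = genomes.donor[iv[0]:iv[1]]
        res = edlib.align(c.seq, window, task="distance")
        cols = max(len(c.seq), len(window))
        dist_sum += res["editDistance"]
        col_sum += cols
    coverage = 100.0 * union_length(donor_ivs) / len(genomes.donor)
    identity = 100.0 * (1.0 - dist_sum / col_sum) if col_sum else 0.0

    # backbone tiling: drop contigs whose anchor is contained in another's
    backbone: List[Contig] = []
    max_end = -1
    for start, end, c in sorted(anchored, key=lambda t: (t[0], -t[1])):
        if end > max_end:
            backbone.append(c)
            max_end = end
    true_pairs = [
        (backbone[i].contig_id, backbone[i + 1].contig_id)
        for i in range(len(backbone) - 1)
    ]
    joined = set()
    for path in paths:
        for x, y in zip(path.elements, path.elements[1:]):
            if x.orientation == "+" and y.orientation == "+":
                joined.add((x.contig_id, y.contig_id))
            if x.orientation == "-" and y.orientation == "-":
                joined.add((y.contig_id, x.contig_id))
    correct = sum(1 for pair in true_pairs if pair in joined)
    if true_pairs:
        adjacency = 100.0 * correct / len(true_pairs)
    else:
        adjacency = 100.0
    return RecoveryReport(
        donor_coverage_pct=coverage,
        consensus_identity_pct=identity,
        adjacency_accuracy_pct=adjacency,
        n_true_adjacent_pairs=len(true_pairs),
        n_correct_joins=correct,
    )
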