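"""Readers and writers for the standard formats the pipeline touches.

Everything downstream consumes only the in-memory types defined here:

* :class:`QualityRead` — a read with per-base Phred qualities (FASTQ).
* :class:`Placement` — a read's alignment interval on the reference with its
  reference-projected bases (SAM, via CIGAR projection).
* :class:`RepeatRecord` — a RepeatMasker hit mapped onto a closed family set.
* :class:`AlignmentSegment` — one whole-genome alignment segment (PAF).

All internal coordinates are 0-based half-open; 1-based conventions appear
only at the SAM/AGP serialization edges.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Sequence, Tuple, Union

import pysam

GAP = "-"

#: closed repeat family set; RepeatMasker class/family strings map onto it
REPEAT_FAMILIES = (
    "LINE",
    "LTR",
    "SINE",
    "Simple repeat",
    "Satellite",
    "ncRNA",
    "Others",
)

_NCRNA_CLASSES = {"rRNA", "scRNA", "snRNA", "srpRNA", "tRNA", "trRNA", "ncRNA"}


@dataclass(slots=True)
class QualityRead:
    """A read's bases and per-base Phred qualities with provenance labels.

    ``quals`` is stored as raw Phred values (``bytes`` for compactness;
    indexing yields integers).  Invariant: ``len(bases) == len(quals)``.
    """

    read_id: str
    bases: str
    quals: bytes
    run_label: str = ""
    mate_role: str = "fragment"  # fragment | mate_first | mate_second

    def __post_init__(self) -> None:
        if isinstance(self.quals, (list, tuple)):
            self.quals = bytes(self.quals)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if not self.read_id:
            raise ValueError("read_id must be non-empty")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def pair_stem(self) -> str:
        return self.read_id.rsplit("/", 1)[0]


@dataclass(slots=True)
class Placement:
    """One read's alignment on the reference, projected to reference columns.

    ``proj_bases`` holds one symbol per reference column covered: aligned read
    bases for M/=/X columns and :data:`GAP` for deletion columns; insertions
    relative to the reference are dropped.  ``proj_quals`` mirrors it with raw
    Phred values (0 at gap columns) when qualities were available.
    """

    read_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    proj_bases: str
    mapq: int = 0
    proj_quals: Optional[bytes] = None

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(f"{self.read_id}: empty reference interval")
        if len(self.proj_bases) != self.ref_end - self.ref_start:
            raise ValueError(
                f"{self.read_id}: proj_bases length {len(self.proj_bases)} != "
                f"interval length {self.ref_end - self.ref_start}"
            )

    @property
    def pair_stem(self) -> str:
        return self.read_id.rsplit("/", 1)[0]


@dataclass(slots=True)
class RepeatRecord:
    family: str
    ref_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.family not in REPEAT_FAMILIES:
            raise ValueError(f"unknown repeat family {self.family!r}")
        if self.start >= self.end:
            raise ValueError("empty repeat interval")


@dataclass(slots=True)
class AlignmentSegment:
    ref_name: str
    ref_start: int
    ref_end: int
    qry_name: str
    qry_start: int
    qry_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start < 1 or self.qry_end - self.qry_start < 1:
            raise ValueError("alignment segment must cover >=1 bp in both genomes")


@dataclass(slots=True)
class AssemblyRecord:
    """A FASTA record, optionally with an AGP component layout.

    ``components`` is a list of parts tiling the sequence:
    ``("W", component_id, component_length, orientation)`` for sequence
    components and ``("N", gap_length)`` for scaffold gaps.
    """

    name: str
    seq: str
    components: Optional[List[tuple]] = None


# ---------------------------------------------------------------------------
# FASTQ

def read_reads(path: Union[str, Path], run_label: Optional[str] = None) -> Iterator[QualityRead]:
    """Stream QualityReads from a Phred+33 FASTQ file, order preserved.

    Mate roles are inferred from ``/1`` / ``/2`` read-id suffixes; everything
    else is labelled ``fragment``.  A record whose base and quality strings
    disagree in length raises a :class:`ValueError` naming the read.
    """
    label = run_label if run_label is not None else Path(path).stem
    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            qual = entry.quality
            if qual is None:
                raise ValueError(f"read {entry.name!r}: missing quality string")
            seq = entry.sequence or ""
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {entry.name!r}: {len(seq)} bases but {len(qual)} quality symbols"
                )
            role = "fragment"
            if entry.name.endswith("/1"):
                role = "mate_first"
            elif entry.name.endswith("/2"):
                role = "mate_second"
            yield QualityRead(
                read_id=entry.name,
                bases=seq,
                quals=bytes(c - 33 for c in qual.encode()),
                run_label=label,
                mate_role=role,
            )


def write_reads(reads: Iterable[QualityRead], path: Union[str, Path]) -> int:
    """Write Phred+33 FASTQ; returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n")
            fh.write(bytes(q + 33 for q in r.quals).decode("ascii"))
            fh.write("\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM

class AlignmentsResult(NamedTuple):
    placements: List[Placement]
    unmapped: List[str]
    rejected: int  # secondary/supplementary records, ignored by design


# CIGAR opcodes (pysam numeric codes)
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H = 0, 1, 2, 3, 4, 5
_OP_EQ, _OP_X = 7, 8


def _project(read) -> Tuple[str, Optional[bytes]]:
    """Project a mapped SAM record onto reference columns.

    M/=/X consume read and reference; D emits gap symbols; I is dropped;
    S consumes the read only; H consumes nothing.  Anything else is an error.
    """
    seq = read.query_sequence
    if seq is None:
        raise ValueError(f"{read.query_name}: mapped record without SEQ")
    quals = read.query_qualities  # array of raw Phred values or None
    cig = read.cigartuples
    if cig is None:
        raise ValueError(f"{read.query_name}: mapped record without CIGAR")
    if len(cig) == 1 and cig[0][0] in (_OP_M, _OP_EQ, _OP_X):
        return seq, (bytes(quals) if quals is not None else None)
    parts: List[str] = []
    qparts: List[bytes] = []
    qpos = 0
    for op, length in cig:
        if op in (_OP_M, _OP_EQ, _OP_X):
            parts.append(seq[qpos:qpos + length])
            if quals is not None:
                qparts.append(bytes(quals[qpos:qpos + length]))
            qpos += length
        elif op == _OP_D:
            parts.append(GAP * length)
            qparts.append(b"\x00" * length)
        elif op in (_OP_I, _OP_S):
            qpos += length
        elif op == _OP_H:
            pass
        else:
            raise ValueError(f"{read.query_name}: unsupported CIGAR opcode {op}")
    proj_quals = b"".join(qparts) if quals is not None else None
    return "".join(parts), proj_quals


def read_alignments(path: Union[str, Path], min_mapq: int = 0) -> AlignmentsResult:
    """Parse a SAM file into Placements plus unmapped read ids.

    Mapped primary records with ``MAPQ >= min_mapq`` become Placements via
    CIGAR projection; flag-4 and sub-threshold records are returned as
    unmapped ids; secondary/supplementary records are ignored (counted in
    ``rejected``) so each read contributes at most one Placement.
    """
    placements: List[Placement] = []
    unmapped: List[str] = []
    rejected = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                rejected += 1
                continue
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                unmapped.append(rec.query_name)
                continue
            proj, proj_quals = _project(rec)
            placements.append(
                Placement(
                    read_id=rec.query_name,
                    ref_name=rec.reference_name,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_start + len(proj),
                    strand="-" if rec.is_reverse else "+",
                    proj_bases=proj,
                    mapq=rec.mapping_quality,
                    proj_quals=proj_quals,
                )
            )
    return AlignmentsResult(placements, unmapped, rejected)


# ---------------------------------------------------------------------------
# FASTA / AGP

def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    out: Dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            out[entry.name] = entry.sequence or ""
    return out


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def write_assembly(
    records: Iterable[AssemblyRecord],
    fasta_path: Union[str, Path],
    agp_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write sequences as 60-column FASTA and, optionally, AGP v2.1.

    AGP coordinates are 1-based inclusive; sequence components become W lines
    and gaps become N lines (gap_type ``scaffold``, linkage ``yes``, evidence
    ``paired-ends``).  Components must tile each object exactly.
    """
    records = list(records)
    with open(fasta_path, "w") as fh:
        for rec in records:
            if not rec.seq:
                raise ValueError(f"{rec.name}: empty sequence")
            fh.write(f">{rec.name}\n{_wrap(rec.seq)}\n")
    if agp_path is None:
        return
    with open(agp_path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for rec in records:
            comps = rec.components
            if comps is None:
                comps = [("W", rec.name, len(rec.seq), "+")]
            pos = 0
            for part_no, comp in enumerate(comps, start=1):
                if comp[0] == "W":
                    _, comp_id, comp_len, orient = comp
                    fh.write(
                        f"{rec.name}\t{pos + 1}\t{pos + comp_len}\t{part_no}\tW\t"
                        f"{comp_id}\t1\t{comp_len}\t{orient}\n"
                    )
                    pos += comp_len
                elif comp[0] == "N":
                    gap_len = comp[1]
                    fh.write(
                        f"{rec.name}\t{pos + 1}\t{pos + gap_len}\t{part_no}\tN\t"
                        f"{gap_len}\tscaffold\tyes\tpaired-ends\n"
                    )
                    pos += gap_len
                else:
                    raise ValueError(f"unknown component kind {comp[0]!r}")
            if pos != len(rec.seq):
                raise ValueError(
                    f"{rec.name}: components tile {pos} bp but sequence is "
                    f"{len(rec.seq)} bp"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out and PAF

def map_repeat_family(class_family: str) -> str:
    """Map a RepeatMasker class/family string onto the closed family set."""
    head = class_family.split("/", 1)[0]
    if head in ("LINE", "SINE", "LTR"):
        return head
    if head in ("Simple_repeat", "Low_complexity"):
        return "Simple repeat"
    if head.startswith("Satellite"):
        return "Satellite"
    if head in _NCRNA_CLASSES:
        return "ncRNA"
    return "Others"


def _parse_repeatmasker(lines: Iterable[str]) -> Tuple[List[RepeatRecord], int]:
    records: List[RepeatRecord] = []
    rejects = 0
    for line in lines:
        fields = line.split()
        if not fields:
            continue
        if fields[0] in ("SW", "score"):  # the standard 3-line header
            continue
        try:
            ref_name = fields[4]
            start = int(fields[5]) - 1  # .out begin is 1-based
            end = int(fields[6])
            family = map_repeat_family(fields[10])
            records.append(RepeatRecord(family, ref_name, start, end))
        except (IndexError, ValueError):
            warnings.warn(f"skipping unparseable RepeatMasker line: {line.rstrip()!r}")
            rejects += 1
    return records, rejects


def _parse_paf(lines: Iterable[str]) -> Tuple[List[AlignmentSegment], int]:
    segments: List[AlignmentSegment] = []
    rejects = 0
    for line in lines:
        if not line.strip():
            continue
        fields = line.split()
        try:
            if len(fields) < 12:
                raise ValueError("fewer than 12 PAF columns")
            segments.append(
                AlignmentSegment(
                    ref_name=fields[5],
                    ref_start=int(fields[7]),
                    ref_end=int(fields[8]),
                    qry_name=fields[0],
                    qry_start=int(fields[2]),
                    qry_end=int(fields[3]),
                    strand=fields[4],
                )
            )
        except (IndexError, ValueError):
            warnings.warn(f"skipping unparseable PAF line: {line.rstrip()!r}")
            rejects += 1
    return segments, rejects


def read_annotations(path: Union[str, Path], kind: str):
    """Parse annotation input; returns ``(records, n_rejected)``.

    ``kind`` is ``repeatmasker_out`` (RepeatMasker .out; class/family strings
    collapsed onto :data:`REPEAT_FAMILIES`) or ``paf`` (already 0-based
    half-open; strand and coordinates preserved).  Unparseable lines are
    skipped with a warning and counted.
    """
    with open(path) as fh:
        if kind == "repeatmasker_out":
            return _parse_repeatmasker(fh)
        if kind == "paf":
            return _parse_paf(fh)
    raise ValueError(f"unknown annotation kind {kind!r}")
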