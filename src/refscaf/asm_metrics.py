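"""Assembly statistics, repeat-family summaries, and report generation.

N50/L50 follow the standard definition: sort record lengths descending and
take the minimal prefix holding at least half the total; N50 is the smallest
length in that prefix and L50 its size.  Repeat content is measured as
genomic coverage — intervals of one family are unioned per reference
sequence before summing, so nested or double-reported hits are not counted
twice.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

from ._util import union_length
from .io_formats import REPEAT_FAMILIES, AssemblyRecord, RepeatRecord


@dataclass(slots=True)
class AssemblyStats:
    total_len: int
    ungapped_len: int
    n_records: int
    n50: int
    l50: int
    max_len: int
    mean_len: float


@dataclass(slots=True)
class RepeatSummary:
    family_bp: Dict[str, int]
    total_bp: int
    genome_len: int
    fraction_of_genome: float

    def family_fraction_of_repeats(self, family: str) -> float:
        if self.total_bp == 0:
            return 0.0
        return self.family_bp[family] / self.total_bp


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1)."""
    return math.floor(x + 0.5)


def nx_lx(lengths: Sequence[int], fraction: float = 0.5) -> Tuple[int, int]:
    """(Nx, Lx) of a length set for the given cumulative fraction."""
    if not lengths:
        raise ValueError("Nx/Lx are undefined for an empty length set")
    if any(l < 1 for l in lengths):
        raise ValueError("all lengths must be >= 1")
    ordered = sorted(lengths, reverse=True)
    target = fraction * sum(ordered)
    acc = 0
    for i, l in enumerate(ordered, start=1):
        acc += l
        if acc >= target:
            return l, i
    return ordered[-1], len(ordered)  # fraction > 1 guard


def assembly_stats(records: Iterable[Union[AssemblyRecord, Tuple[str, str], str]]) -> AssemblyStats:
    """Compute Table-2-style statistics over FASTA records.

    Accepts AssemblyRecords, (name, seq) pairs, or bare sequences.  Ungapped
    length excludes ``N``/``n`` symbols only; IUPAC ambiguity codes count as
    sequence.
    """
    seqs: List[str] = []
    for rec in records:
        if isinstance(rec, AssemblyRecord):
            seqs.append(rec.seq)
        elif isinstance(rec, tuple):
            seqs.append(rec[1])
        else:
            seqs.append(rec)
    if not seqs:
        raise ValueError("no records")
    lengths = [len(s) for s in seqs]
    total = sum(lengths)
    n50, l50 = nx_lx(lengths, 0.5)
    return AssemblyStats(
        total_len=total,
        ungapped_len=total - sum(s.count("N") + s.count("n") for s in seqs),
        n_records=len(seqs),
        n50=n50,
        l50=l50,
        max_len=max(lengths),
        mean_len=total / len(seqs),
    )


def repeat_summary(records: Iterable[RepeatRecord], genome_len: int) -> RepeatSummary:
    """Per-family repeat coverage (bp) and fraction of the genome.

    Overlapping records of the same family are merged (union coverage) per
    reference sequence before summing.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    by_key: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for r in records:
        by_key.setdefault((r.family, r.ref_name), []).append((r.start, r.end))
    family_bp = {fam: 0 for fam in REPEAT_FAMILIES}
    for (fam, _ref), ivs in by_key.items():
        family_bp[fam] += union_length(ivs)
    total = sum(family_bp.values())
    return RepeatSummary(
        family_bp=family_bp,
        total_bp=total,
        genome_len=genome_len,
        fraction_of_genome=total / genome_len,
    )


def coverage_fold(total_yield: int, genome_len: int) -> float:
    """Sequencing depth: total read bases over genome length."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    return total_yield / genome_len


def _pct(x: float) -> str:
    return f"{100 * x:.1f}\t{round_half_up(100 * x)}"


def report(stats: AssemblyStats, summary: RepeatSummary = None) -> str:
    """Deterministic TSV report; percentages carry 1-decimal and integer forms."""
    lines = [
        "metric\tvalue",
        f"total_length\t{stats.total_len}",
        f"ungapped_length\t{stats.ungapped_len}",
        f"n_records\t{stats.n_records}",
        f"n50\t{stats.n50}",
        f"l50\t{stats.l50}",
        f"max_length\t{stats.max_len}",
        f"mean_length\t{stats.mean_len:.1f}",
    ]
    if summary is not None:
        lines.append("repeat_family\tbp\tpct_of_repeats\tpct_of_repeats_int")
        for fam in REPEAT_FAMILIES:
            bp = summary.family_bp[fam]
            frac = summary.family_fraction_of_repeats(fam)
            lines.append(f"{fam}\t{bp}\t{_pct(frac)}")
        lines.append(f"Total\t{summary.total_bp}\t{_pct(1.0 if summary.total_bp else 0.0)}")
        lines.append(
            f"repeat_fraction_of_genome\t{summary.total_bp}\t{_pct(summary.fraction_of_genome)}"
        )
    return "\n".join(lines) + "\n"
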