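"""Phred-threshold read trimming and per-run statistics.

The trimming rule truncates a read immediately before the first base whose
quality drops below a floor (default Q15) — the offending base and everything
after it are removed — and discards reads whose surviving prefix is shorter
than a minimum length (default 30 bp).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io_formats import QualityRead

#: marker returned by :func:`trim_read` for reads falling below ``min_len``
DISCARD = None


@dataclass(frozen=True, slots=True)
class TrimPolicy:
    q_floor: int = 15
    min_len: int = 30

    def __post_init__(self) -> None:
        if self.q_floor < 0 or self.min_len < 1:
            raise ValueError("q_floor must be >= 0 and min_len >= 1")


@dataclass(slots=True)
class RunStats:
    """Read-count and length statistics for one run (or run group)."""

    run_label: str
    n_reads: int
    total_bases: int
    mean_len: float  # NaN when n_reads == 0
    median_len: float  # NaN when n_reads == 0


_BELOW_FLOOR_TABLES: Dict[int, bytes] = {}


def _below_floor_table(floor: int) -> bytes:
    # maps Phred bytes below the floor to 0x00, everything else to 0x01,
    # so the first sub-threshold base is a C-speed bytes.find
    table = _BELOW_FLOOR_TABLES.get(floor)
    if table is None:
        table = bytes(0 if q < floor else 1 for q in range(256))
        _BELOW_FLOOR_TABLES[floor] = table
    return table


def trim_read(read: QualityRead, policy: TrimPolicy = TrimPolicy()) -> Optional[QualityRead]:
    """Apply the quality floor; returns the trimmed read or :data:`DISCARD`.

    The output is the prefix ending immediately before the first base with
    quality < ``q_floor``; a read with no sub-threshold base is returned
    unchanged (same object).
    """
    cut = read.quals.translate(_below_floor_table(policy.q_floor)).find(0)
    if cut < 0:
        cut = len(read.quals)
    if cut < policy.min_len:
        return DISCARD
    if cut == len(read):
        return read
    return QualityRead(
        read_id=read.read_id,
        bases=read.bases[:cut],
        quals=read.quals[:cut],
        run_label=read.run_label,
        mate_role=read.mate_role,
    )


def _median(sorted_vals: Sequence[int]) -> float:
    n = len(sorted_vals)
    if n == 0:
        return math.nan
    mid = n // 2
    if n % 2:
        return float(sorted_vals[mid])
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0


def _stats(label: str, lengths: List[int]) -> RunStats:
    n = len(lengths)
    total = sum(lengths)
    lengths.sort()
    return RunStats(
        run_label=label,
        n_reads=n,
        total_bases=total,
        mean_len=(total / n) if n else math.nan,
        median_len=_median(lengths),
    )


def trim_set(
    reads: Iterable[QualityRead], policy: TrimPolicy = TrimPolicy()
) -> Tuple[List[QualityRead], Dict[str, RunStats], Dict[str, RunStats]]:
    """Trim a read set; returns (retained reads, Q0 stats, post-trim stats).

    Statistics are grouped per ``run_label``: the Q0 dictionaries describe all
    input reads before trimming, the policy dictionaries only the retained
    reads.  A run whose reads are all discarded still appears with
    ``n_reads=0`` and NaN mean/median.
    """
    retained: List[QualityRead] = []
    before: Dict[str, List[int]] = {}
    after: Dict[str, List[int]] = {}
    for read in reads:
        before.setdefault(read.run_label, []).append(len(read))
        after.setdefault(read.run_label, [])
        trimmed = trim_read(read, policy)
        if trimmed is not DISCARD:
            retained.append(trimmed)
            after[read.run_label].append(len(trimmed))
    stats_q0 = {label: _stats(label, lens) for label, lens in before.items()}
    stats_q = {label: _stats(label, lens) for label, lens in after.items()}
    return retained, stats_q0, stats_q


def enforce_pair_integrity(retained: Iterable[QualityRead]) -> List[QualityRead]:
    """Demote mates whose partner was discarded to fragment status.

    Mates are trimmed independently; a pair survives as a pair only when both
    mates are retained, otherwise the survivor keeps its sequence but is
    re-labelled ``fragment`` so it no longer participates in pairing.
    """
    retained = list(retained)
    roles: Dict[str, set] = {}
    for r in retained:
        if r.mate_role != "fragment":
            roles.setdefault(r.pair_stem, set()).add(r.mate_role)
    out: List[QualityRead] = []
    for r in retained:
        if r.mate_role != "fragment" and len(roles.get(r.pair_stem, ())) < 2:
            out.append(
                QualityRead(r.read_id, r.bases, r.quals, r.run_label, "fragment")
            )
        else:
            out.append(r)
    return out


def percent_retained(stats_q0: RunStats, stats_q: RunStats) -> float:
    """100 * retained reads / input reads (same read universe)."""
    if stats_q0.n_reads == 0:
        raise ValueError("cannot compute retention over an empty input set")
    return 100.0 * stats_q.n_reads / stats_q0.n_reads


def format_stats_table(
    stats_q0: Dict[str, RunStats],
    stats_q: Dict[str, RunStats],
    floor_median: bool = False,
) -> str:
    """Render per-run statistics as a TSV table.

    ``floor_median`` reports medians truncated to integers, matching tools
    that print integer medians for even-sized runs.
    """
    def fmt(x: float) -> str:
        if math.isnan(x):
            return "NA"
        return str(int(x)) if floor_median else f"{x:.2f}"

    lines = [
        "run\treads_q0\tbases_q0\tmean_q0\tmedian_q0\t"
        "reads_trim\tbases_trim\tmean_trim\tmedian_trim\tpct_reads_retained"
    ]
    for label in stats_q0:
        a, b = stats_q0[label], stats_q[label]
        pct = 100.0 * b.n_reads / a.n_reads if a.n_reads else math.nan
        lines.append(
            f"{label}\t{a.n_reads}\t{a.total_bases}\t{fmt(a.mean_len)}\t{fmt(a.median_len)}\t"
            f"{b.n_reads}\t{b.total_bases}\t{fmt(b.mean_len)}\t{fmt(b.median_len)}\t"
            f"{pct:.1f}"
        )
    return "\n".join(lines) + "\n"
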