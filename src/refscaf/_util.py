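"""Small shared helpers: interval unions and reverse complement."""
from __future__ import annotations

from typing import Iterable, List, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge half-open intervals into a sorted disjoint union."""
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
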