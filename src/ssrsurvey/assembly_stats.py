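"""Assembly summary statistics: Nx lengths, counts, maxima, filtered GC content.

Consumes any FASTA; the assembler that produced it is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import SequenceRecord

__all__ = ["AssemblySummary", "nx_length", "gc_content", "summarize_assembly"]


@dataclass(frozen=True)
class AssemblySummary:
    total_length_bp: int
    total_number: int
    number_gt_2kb: int
    max_length_bp: int
    n50_bp: int
    n90_bp: int
    gc_pct: float

    def __post_init__(self) -> None:
        if not (self.n90_bp <= self.n50_bp <= self.max_length_bp):
            raise ValueError("require N90 <= N50 <= max length")
        if self.number_gt_2kb > self.total_number:
            raise ValueError("count > 2 kb exceeds total count")


def nx_length(lengths: Sequence[int], x: float) -> int:
    """Nx: sort descending, return the length at which the cumulative sum
    first reaches x % of the total."""
    if not lengths:
        raise ValueError("empty length list")
    if not (0 < x < 100):
        raise ValueError("x must be in (0, 100)")
    if any(l < 1 for l in lengths):
        raise ValueError("lengths must be >= 1")
    arr = np.sort(np.asarray(lengths))[::-1]
    cum = np.cumsum(arr)
    target = x / 100.0 * cum[-1]
    idx = int(np.searchsorted(cum, target))
    return int(arr[idx])


def gc_content(records: Sequence[SequenceRecord], min_len: int = 500) -> float:
    """Pooled GC % over records of length >= ``min_len``; N bases excluded
    from both numerator and denominator."""
    passing = [r for r in records if len(r) >= min_len]
    if not passing:
        raise ValueError(f"no record passes the length filter (>= {min_len} bp)")
    gc = 0
    acgt = 0
    for rec in passing:
        seq = rec.residues
        gc += seq.count("G") + seq.count("C")
        acgt += len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("no called bases among passing records")
    return 100.0 * gc / acgt


def summarize_assembly(
    records: Sequence[SequenceRecord], gc_min_len: int = 500
) -> AssemblySummary:
    if not records:
        raise ValueError("no records")
    lengths = [len(r) for r in records]
    return AssemblySummary(
        total_length_bp=sum(lengths),
        total_number=len(lengths),
        number_gt_2kb=sum(1 for l in lengths if l > 2000),
        max_length_bp=max(lengths),
        n50_bp=nx_length(lengths, 50),
        n90_bp=nx_length(lengths, 90),
        gc_pct=gc_content(records, min_len=gc_min_len),
    )
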