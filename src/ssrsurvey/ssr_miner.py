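"""MISA-style mining of perfect simple sequence repeats (SSRs).

A locus is a maximal run of a primitive 1-6 bp motif repeated at least the
per-period minimum number of times (defaults 10/6/5/5/5/5 for mono- through
hexanucleotides), found in scaffolds passing a length filter (default
>= 1000 bp).  Motifs are grouped into canonical classes under cyclic
rotation and reverse complement (e.g. TAT, ATA, AAT, ATT, TTA, TAA all
belong to "AAT/ATT").  Coordinates are 1-based inclusive; runs containing N
are broken at the N; partial trailing units are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .io_formats import SequenceRecord

__all__ = [
    "SSRLocus",
    "MotifDistribution",
    "DEFAULT_MIN_REPEATS",
    "PERIOD_NAMES",
    "REPEAT_BINS",
    "is_primitive",
    "canonical_class",
    "find_ssrs",
    "summarize_ssrs",
    "share_pct",
]

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

PERIOD_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

#: Repeat-count bins; the first bin also absorbs any count below 5.
REPEAT_BINS = ("5", "6", "7", "8", "9", "10", "11-20", ">20")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number power of a shorter string."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Canonical "X/Y" class of a repeat unit.

    X is the lexicographically smallest string among all rotations of the
    motif and all rotations of its reverse complement; Y is the reverse
    complement of X.
    """
    if not (1 <= len(motif) <= 6):
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = _revcomp(motif)
    candidates = [
        s[i:] + s[:i] for s in (motif, rc) for i in range(len(motif))
    ]
    x = min(candidates)
    return f"{x}/{_revcomp(x)}"


@dataclass
class SSRLocus:
    """One perfect tandem repeat; ``start``/``end`` are 1-based inclusive."""

    scaffold_id: str
    start: int
    end: int
    period: int
    motif: str
    repeat_count: int
    canonical_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.period * self.repeat_count:
            raise ValueError(
                f"locus span {self.end - self.start + 1} != "
                f"period {self.period} x repeats {self.repeat_count}"
            )
        if not self.canonical_class:
            self.canonical_class = canonical_class(self.motif)

    @property
    def type(self) -> str:
        return PERIOD_NAMES[self.period]

    def key(self) -> tuple:
        return (self.scaffold_id, self.start, self.end, self.period, self.motif)


def _scan_segment(
    seq: str, offset: int, scaffold_id: str, min_repeats: Mapping[int, int]
) -> list[SSRLocus]:
    """All maximal qualifying runs in one N-free segment.

    ``offset`` is the 0-based position of the segment start on the scaffold.
    """
    n = len(seq)
    candidates: list[SSRLocus] = []
    for period, min_rep in sorted(min_repeats.items()):
        i = 0
        while i + period < n:
            if seq[i] != seq[i + period]:
                i += 1
                continue
            # extend the period-p run starting at i
            j = i
            while j + period < n and seq[j] == seq[j + period]:
                j += 1
            run_len = (j - i) + period  # matched region plus one full unit
            count = run_len // period
            motif = seq[i : i + period]
            if count >= min_rep and is_primitive(motif):
                start0 = i
                end0 = i + count * period - 1  # trim partial trailing unit
                candidates.append(
                    SSRLocus(
                        scaffold_id=scaffold_id,
                        start=offset + start0 + 1,
                        end=offset + end0 + 1,
                        period=period,
                        motif=motif,
                        repeat_count=count,
                    )
                )
            i = j + 1
    return candidates


def _resolve_overlaps(candidates: list[SSRLocus]) -> list[SSRLocus]:
    """Greedy non-overlapping selection: longer run first, then smaller
    period, then leftmost.  Primitivity already guarantees a run is only
    reported at its smallest period; this handles runs that merely share
    boundary bases."""
    ordered = sorted(
        candidates, key=lambda l: (-(l.end - l.start + 1), l.period, l.start)
    )
    kept: list[SSRLocus] = []
    for cand in ordered:
        if all(
            cand.end < k.start or cand.start > k.end
            for k in kept
            if k.scaffold_id == cand.scaffold_id
        ):
            kept.append(cand)
    kept.sort(key=lambda l: (l.scaffold_id, l.start))
    return kept


def find_ssrs(
    records: Sequence[SequenceRecord],
    min_repeats: Optional[Mapping[int, int]] = None,
    min_scaffold_len: int = 1000,
) -> list[SSRLocus]:
    """Mine perfect SSRs from scaffolds of length >= ``min_scaffold_len``.

    Returns loci sorted by (scaffold, start); no two loci on one scaffold
    overlap.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    if any(v < 2 for v in min_repeats.values()):
        raise ValueError("repeat thresholds must be >= 2")
    loci: list[SSRLocus] = []
    for rec in records:
        if len(rec) < min_scaffold_len:
            continue
        candidates: list[SSRLocus] = []
        offset = 0
        for segment in rec.residues.split("N"):
            if segment:
                candidates.extend(_scan_segment(segment, offset, rec.id, min_repeats))
            offset += len(segment) + 1
        loci.extend(_resolve_overlaps(candidates))
    loci.sort(key=lambda l: (l.scaffold_id, l.start))
    return loci


def _bin_label(repeat_count: int) -> str:
    if repeat_count <= 5:
        return "5"
    if repeat_count <= 10:
        return str(repeat_count)
    if repeat_count <= 20:
        return "11-20"
    return ">20"


def share_pct(part: float, whole: float) -> float:
    """Percentage of ``part`` in ``whole``, rounded to 2 decimals."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, 2)


@dataclass
class MotifDistribution:
    """Canonical-class x repeat-count-bin tally (the motif-distribution table).

    ``cells[(period, class)][bin]`` holds locus counts; per-period totals and
    the grand total are maintained alongside.
    """

    cells: dict[tuple[int, str], dict[str, int]]
    period_totals: dict[int, int]
    grand_total: int

    @classmethod
    def from_loci(cls, loci: Sequence[SSRLocus]) -> "MotifDistribution":
        cells: dict[tuple[int, str], dict[str, int]] = {}
        period_totals: dict[int, int] = {}
        for loc in loci:
            key = (loc.period, loc.canonical_class)
            row = cells.setdefault(key, {b: 0 for b in REPEAT_BINS})
            row[_bin_label(loc.repeat_count)] += 1
            period_totals[loc.period] = period_totals.get(loc.period, 0) + 1
        return cls(
            cells=cells, period_totals=period_totals, grand_total=len(loci)
        )

    def class_total(self, period: int, canonical: str) -> int:
        return sum(self.cells.get((period, canonical), {}).values())

    def class_share_of_period(self, period: int, canonical: str) -> float:
        """Class count as % of its period's total."""
        return share_pct(
            self.class_total(period, canonical), self.period_totals.get(period, 0)
        )

    def period_share_of_total(self, period: int) -> float:
        """Period total as % of the grand total."""
        return share_pct(self.period_totals.get(period, 0), self.grand_total)


def mean_distance_kb(total_scanned_length: float, n_loci: int) -> Optional[float]:
    """Mean inter-SSR distance in kb (2 dp); None when there are no loci."""
    if total_scanned_length <= 0:
        raise ValueError("scanned length must be positive")
    if n_loci == 0:
        return None
    return round(total_scanned_length / n_loci / 1000.0, 2)


def summarize_ssrs(
    loci: Sequence[SSRLocus], total_scanned_length: float
) -> tuple[MotifDistribution, Optional[float]]:
    """Motif-distribution table plus the mean inter-locus distance in kb."""
    dist = MotifDistribution.from_loci(loci)
    return dist, mean_distance_kb(total_scanned_length, len(loci))
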