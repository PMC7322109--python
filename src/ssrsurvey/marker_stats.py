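"""Per-locus marker diversity statistics: Na, Ho, He and PIC.

PIC here is the gene-diversity form 1 - sum(f_i^2) over allele frequencies
f_i, which coincides with the biased expected heterozygosity; the unbiased
(sample-size-corrected) He multiplies by 2n/(2n-1).  Loci are classed by the
Botstein thresholds: low (PIC < 0.25), moderate (0.25 <= PIC <= 0.5), high
(PIC > 0.5) — boundary values fall in the moderate class.  Missing calls are
excluded listwise per locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "LocusUntypedError",
    "LocusStats",
    "PanelSummary",
    "allele_frequencies",
    "locus_stats",
    "compute_panel",
    "summarize_panel",
    "botstein_class",
]


class LocusUntypedError(ValueError):
    """Every call at the locus is missing in the chosen subset."""


def botstein_class(pic: float) -> str:
    if pic < 0.25:
        return "low"
    if pic > 0.5:
        return "high"
    return "moderate"


@dataclass(frozen=True)
class LocusStats:
    locus: str
    n_typed: int
    na: int
    ho: float
    he_biased: float
    he_unbiased: float
    pic: float

    def __post_init__(self) -> None:
        if self.n_typed >= 1 and self.na < 1:
            raise ValueError("Na must be >= 1 for a typed locus")
        if not (0.0 <= self.ho <= 1.0):
            raise ValueError("Ho outside [0, 1]")

    @property
    def botstein(self) -> str:
        return botstein_class(self.pic)


@dataclass(frozen=True)
class PanelSummary:
    n_loci: int
    total_alleles: int
    mean_na: float
    mean_ho: float
    mean_he: float
    mean_pic: float
    n_low: int
    n_moderate: int
    n_high: int


def _subset(matrix: GenotypeMatrix, individuals: Optional[Sequence[str]]) -> list[str]:
    if individuals is None:
        return list(matrix.individuals)
    unknown = set(individuals) - set(matrix.individuals)
    if unknown:
        raise ValueError(f"unknown individuals: {sorted(unknown)}")
    return list(individuals)


def allele_frequencies(
    matrix: GenotypeMatrix,
    locus: str,
    individuals: Optional[Sequence[str]] = None,
) -> dict[int, float]:
    """Allele frequencies at one locus over a subset of individuals.

    Each non-missing diploid call contributes two allele observations.
    """
    if locus not in matrix.loci:
        raise ValueError(f"unknown locus {locus!r}")
    counts: dict[int, int] = {}
    n_obs = 0
    for ind in _subset(matrix, individuals):
        call = matrix.call(ind, locus)
        if call is MISSING:
            continue
        for allele in call:
            counts[allele] = counts.get(allele, 0) + 1
            n_obs += 1
    if n_obs == 0:
        raise LocusUntypedError(f"locus {locus!r} untyped in subset")
    return {a: c / n_obs for a, c in sorted(counts.items())}


def locus_stats(
    matrix: GenotypeMatrix,
    locus: str,
    individuals: Optional[Sequence[str]] = None,
) -> LocusStats:
    freqs = allele_frequencies(matrix, locus, individuals)
    n_typed = 0
    n_het = 0
    for ind in _subset(matrix, individuals):
        call = matrix.call(ind, locus)
        if call is MISSING:
            continue
        n_typed += 1
        if call[0] != call[1]:
            n_het += 1
    he_biased = 1.0 - sum(f * f for f in freqs.values())
    n2 = 2 * n_typed
    he_unbiased = he_biased * n2 / (n2 - 1) if n2 > 1 else 0.0
    return LocusStats(
        locus=locus,
        n_typed=n_typed,
        na=len(freqs),
        ho=n_het / n_typed,
        he_biased=he_biased,
        he_unbiased=he_unbiased,
        pic=he_biased,
    )


def compute_panel(
    matrix: GenotypeMatrix,
    loci: Optional[Sequence[str]] = None,
    individuals: Optional[Sequence[str]] = None,
    skip_untyped: bool = True,
) -> list[LocusStats]:
    """Stats for every locus; untyped loci are skipped (reported as "-" by
    table writers) unless ``skip_untyped`` is False, in which case they raise."""
    out = []
    for locus in loci if loci is not None else matrix.loci:
        try:
            out.append(locus_stats(matrix, locus, individuals))
        except LocusUntypedError:
            if not skip_untyped:
                raise
    return out


def summarize_panel(stats: Sequence[LocusStats], use_unbiased_he: bool = True) -> PanelSummary:
    """Panel totals and unweighted means over loci, plus the Botstein tally."""
    if not stats:
        raise ValueError("no locus statistics to summarize")
    n = len(stats)
    classes = [s.botstein for s in stats]
    return PanelSummary(
        n_loci=n,
        total_alleles=sum(s.na for s in stats),
        mean_na=sum(s.na for s in stats) / n,
        mean_ho=sum(s.ho for s in stats) / n,
        mean_he=sum(
            (s.he_unbiased if use_unbiased_he else s.he_biased) for s in stats
        )
        / n,
        mean_pic=sum(s.pic for s in stats) / n,
        n_low=classes.count("low"),
        n_moderate=classes.count("moderate"),
        n_high=classes.count("high"),
    )
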