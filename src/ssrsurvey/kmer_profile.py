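"""Genome profiling from a k-mer spectrum.

A k-mer spectrum is the histogram of how many distinct length-k substrings of
a read set occur at each multiplicity (depth).  Its main peak depth
approximates the sequencing coverage of unique genome, so

    genome size = total k-mer observations / peak depth.

Low-depth mass (depth below the first valley) is sequencing error; a
secondary peak at half the main depth is produced by k-mers overlapping
heterozygous sites; a fat tail beyond the main peak is repetitive sequence.
This module estimates genome size (raw and error-revised), the per-base
heterozygosity rate, and the repeat fraction from those three features.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.stats import poisson

from .io_formats import SequenceRecord

__all__ = [
    "KmerHistogram",
    "GenomeProfile",
    "SpectrumUninformativeError",
    "count_kmers",
    "find_error_cutoff",
    "estimate_peak_depth",
    "estimate_genome_size",
    "estimate_heterozygosity",
    "estimate_repeat_fraction",
    "kmer_fraction_to_het_rate",
    "profile_genome",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SpectrumUninformativeError(ValueError):
    """The spectrum has no usable genomic peak."""


@dataclass
class KmerHistogram:
    """Distinct-k-mer counts indexed by depth: ``counts[d]`` = number of
    distinct k-mers observed exactly ``d`` times."""

    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for d, n in self.counts.items():
            if d < 1:
                raise ValueError(f"depth {d} < 1")
            if n < 0:
                raise ValueError(f"negative count at depth {d}")

    @property
    def total_observations(self) -> int:
        """K-mer number: sum of depth x count over all depths."""
        return sum(d * n for d, n in self.counts.items())

    @property
    def total_distinct(self) -> int:
        return sum(self.counts.values())

    def depths(self) -> list[int]:
        return sorted(d for d in self.counts if self.counts[d] > 0)


@dataclass(frozen=True)
class GenomeProfile:
    """The genome characteristics read off one spectrum."""

    k: int
    peak_depth: int
    error_cutoff: int
    genome_size_bp: float
    revised_genome_size_bp: float
    het_rate: Optional[float]
    repeat_fraction: float

    def __post_init__(self) -> None:
        if self.revised_genome_size_bp > self.genome_size_bp:
            raise ValueError("revised size exceeds raw size")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_kmers(
    records: Sequence[SequenceRecord], k: int, canonical: bool = False
) -> KmerHistogram:
    """Tally every N-free length-k window into a depth histogram.

    With ``canonical=True`` a k-mer and its reverse complement are merged
    under the lexicographically smaller of the two forms.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        raise ValueError("no records")
    tally: Counter[str] = Counter()
    for rec in records:
        seq = rec.residues
        for segment in seq.split("N"):
            for i in range(len(segment) - k + 1):
                kmer = segment[i : i + k]
                if canonical:
                    rc = _revcomp(kmer)
                    if rc < kmer:
                        kmer = rc
                tally[kmer] += 1
    if not tally:
        raise ValueError(f"no k-mers: every record is shorter than k={k} (or all N)")
    counts: Counter[int] = Counter(tally.values())
    return KmerHistogram(k=k, counts=dict(counts))


def find_error_cutoff(hist: KmerHistogram) -> int:
    """Depth of the first local minimum of the spectrum, scanning upward.

    All mass at depths below the returned cutoff is classified as sequencing
    error.  The scan runs over the sparse support (depths actually observed).
    A spectrum whose first observed depth is already its global maximum has
    no error component when that depth exceeds 1 (cutoff = that depth), and
    is an uninformative pure-error spectrum when it starts at depth 1 and
    only ever decreases.
    """
    depths = hist.depths()
    if not depths:
        raise SpectrumUninformativeError("empty spectrum")
    if len(depths) == 1:
        if depths[0] == 1:
            raise SpectrumUninformativeError("spectrum uninformative: no genomic peak")
        return depths[0]
    values = [hist.counts[d] for d in depths]
    for i in range(len(values) - 1):
        if values[i] <= values[i + 1]:
            return depths[i]
        if depths[i + 1] > depths[i] + 1:
            # still decreasing across a run of zero-count depths: the valley
            # sits in the gap, right after the error tail
            return depths[i] + 1
    # never rose again
    if depths[0] > 1 and values[0] >= max(values):
        return depths[0]
    raise SpectrumUninformativeError("spectrum uninformative: no genomic peak")


def _local_maxima(depths: np.ndarray, values: np.ndarray) -> list[tuple[int, int]]:
    """(depth, height) of strict-or-plateau local maxima on a dense grid."""
    maxima = []
    n = len(values)
    for i in range(n):
        left = values[i - 1] if i > 0 else -1
        right = values[i + 1] if i < n - 1 else -1
        if values[i] >= left and values[i] >= right and values[i] > min(left, right):
            maxima.append((int(depths[i]), int(values[i])))
    return maxima


def estimate_peak_depth(
    hist: KmerHistogram,
    error_cutoff: int,
    override: Optional[int] = None,
    min_height_frac: float = 0.10,
) -> int:
    """Homozygous-peak depth of the spectrum.

    Detects all local maxima at depth >= ``error_cutoff`` whose height is at
    least ``min_height_frac`` of the tallest.  A heterozygous genome shows a
    peak at half the true depth, often taller than the homozygous peak; so if
    the tallest maximum T is accompanied by a substantial maximum q with
    q ~ 2T (within max(2, 0.1 q), height >= 50 % of T's), q is returned as
    the homozygous peak.  ``override`` bypasses the heuristic entirely.
    """
    if override is not None:
        if override < 1:
            raise ValueError("override depth must be >= 1")
        return override
    depths_sparse = [d for d in hist.depths() if d >= error_cutoff]
    if not depths_sparse:
        raise SpectrumUninformativeError("no mass at or above the error cutoff")
    lo, hi = depths_sparse[0], depths_sparse[-1]
    dense_d = np.arange(lo, hi + 1)
    dense_v = np.array([hist.counts.get(int(d), 0) for d in dense_d])
    maxima = _local_maxima(dense_d, dense_v)
    if not maxima:
        raise SpectrumUninformativeError("spectrum uninformative: no local maximum")
    tallest_height = max(h for _, h in maxima)
    maxima = [(d, h) for d, h in maxima if h >= min_height_frac * tallest_height]
    # collapse jitter: maxima within 3 depth units merge to the tallest
    maxima.sort(key=lambda m: (-m[1], m[0]))
    kept: list[tuple[int, int]] = []
    for d, h in maxima:
        if all(abs(d - kd) > 3 for kd, _ in kept):
            kept.append((d, h))
    t_depth, t_height = kept[0]
    for q_depth, q_height in kept[1:]:
        if abs(q_depth - 2 * t_depth) <= max(2, 0.1 * q_depth) and (
            q_height >= 0.5 * t_height
        ):
            return q_depth
    return t_depth


def estimate_genome_size(
    hist: KmerHistogram, peak_depth: int, error_cutoff: int
) -> tuple[float, float]:
    """(raw, revised) genome size in bp.

    raw = total k-mer observations / peak depth; revised additionally drops
    the erroneous observations below the error cutoff from the numerator.
    """
    if peak_depth < 1:
        raise ValueError("peak depth must be >= 1")
    total = hist.total_observations
    if total == 0:
        raise ValueError("spectrum has no observations")
    erroneous = sum(d * n for d, n in hist.counts.items() if d < error_cutoff)
    return total / peak_depth, (total - erroneous) / peak_depth


def kmer_fraction_to_het_rate(f_het: float, k: int) -> float:
    """Invert f_het = 1 - (1 - r)^k: the fraction of k-mers overlapping a
    heterozygous site implied by a per-base heterozygosity r, assuming
    independent sites."""
    if not (0.0 <= f_het < 1.0):
        raise ValueError("f_het must be in [0, 1)")
    return 1.0 - (1.0 - f_het) ** (1.0 / k)


def estimate_heterozygosity(
    hist: KmerHistogram, peak_depth: int, error_cutoff: int
) -> Optional[float]:
    """Per-base heterozygosity from the half-depth peak.

    Fits a non-negative least-squares mixture of two Poisson components
    (means peak/2 and peak) to the spectrum on cutoff <= d <= 2*peak.  The
    half-depth component holds two k-mer variants per heterozygous site, so
    its fitted count A and the full-depth count B give
    f_het = (A/2) / (A/2 + B), converted to a per-base rate via
    ``kmer_fraction_to_het_rate``.  Returns 0.0 when the half-depth weight is
    not meaningfully positive, None when the fit is degenerate.
    """
    lo = max(error_cutoff, 1)
    hi = 2 * peak_depth
    ds = np.arange(lo, hi + 1)
    ys = np.array([hist.counts.get(int(d), 0) for d in ds], dtype=float)
    if ys.sum() <= 0:
        warnings.warn("heterozygosity not estimable: no mass in fit window")
        return None
    design = np.column_stack(
        [poisson.pmf(ds, peak_depth / 2.0), poisson.pmf(ds, float(peak_depth))]
    )
    try:
        weights, _ = nnls(design, ys)
    except Exception:  # pragma: no cover - nnls failure is pathological
        warnings.warn("heterozygosity not estimable: fit divergence")
        return None
    a, b = float(weights[0]), float(weights[1])
    if a + b <= 0:
        warnings.warn("heterozygosity not estimable: degenerate fit")
        return None
    f_het = (a / 2.0) / (a / 2.0 + b)
    if f_het < 1e-4:
        return 0.0
    return kmer_fraction_to_het_rate(f_het, hist.k)


def estimate_repeat_fraction(
    hist: KmerHistogram, peak_depth: int, error_cutoff: int, multiplier: float = 2.0
) -> float:
    """Share of non-erroneous k-mer observations at depth > multiplier * peak."""
    threshold = multiplier * peak_depth
    repetitive = sum(d * n for d, n in hist.counts.items() if d > threshold)
    erroneous = sum(d * n for d, n in hist.counts.items() if d < error_cutoff)
    genomic = hist.total_observations - erroneous
    if genomic <= 0:
        raise ValueError("no non-erroneous observations")
    return repetitive / genomic


def profile_genome(
    hist: KmerHistogram,
    peak_depth: Optional[int] = None,
    repeat_multiplier: float = 2.0,
) -> GenomeProfile:
    """Run the full estimator chain on one spectrum."""
    cutoff = find_error_cutoff(hist)
    peak = estimate_peak_depth(hist, cutoff, override=peak_depth)
    size, revised = estimate_genome_size(hist, peak, cutoff)
    het = estimate_heterozygosity(hist, peak, cutoff)
    rep = estimate_repeat_fraction(hist, peak, cutoff, multiplier=repeat_multiplier)
    return GenomeProfile(
        k=hist.k,
        peak_depth=peak,
        error_cutoff=cutoff,
        genome_size_bp=size,
        revised_genome_size_bp=revised,
        het_rate=het,
        repeat_fraction=rep,
    )
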