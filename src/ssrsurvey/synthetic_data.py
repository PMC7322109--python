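"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of their spec (seed included):

* scaffolds with planted perfect SSRs (background guaranteed free of
  unplanned qualifying SSRs, so the planted truth table is exactly the
  minable locus set);
* k-mer spectra assembled from error, heterozygous (half-depth),
  homozygous-unique and repeat (2x/4x/8x depth) Poisson components;
* two-population diploid genotype matrices with divergence-controlled
  allele frequencies and missing data, following a Balding-Nichols-style
  model under Hardy-Weinberg sampling within populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import poisson

from .io_formats import MISSING, GenotypeMatrix, SequenceRecord
from .kmer_profile import KmerHistogram
from .ssr_miner import DEFAULT_MIN_REPEATS, SSRLocus, is_primitive

__all__ = [
    "GenomeSimSpec",
    "SpectrumSimSpec",
    "PopSimSpec",
    "simulate_scaffolds",
    "simulate_kmer_histogram",
    "simulate_genotypes",
]

#: Observation-mass weights of the 2x/4x/8x repeat-depth components.  Deep
#: families dominate the observation mass of a highly repetitive genome, so
#: most of the repeat mass sits well beyond twice the main peak.
REPEAT_COPY_WEIGHTS = {2: 0.2, 4: 0.4, 8: 0.4}


@dataclass(frozen=True)
class GenomeSimSpec:
    """Scaffold set with planted perfect SSRs.

    ``planted_ssrs`` entries are (motif, repeat_count, scaffold_index,
    start) with 1-based start coordinates.  Planted loci must be primitive,
    non-overlapping and at least 50 bp from scaffold ends.
    """

    n_scaffolds: int
    length_range: tuple[int, int]
    gc_target: float = 0.38
    planted_ssrs: tuple[tuple[str, int, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1:
            raise ValueError("need at least one scaffold")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length range")
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0, 1)")
        by_scaffold: dict[int, list[tuple[int, int]]] = {}
        for motif, count, sc_idx, start in self.planted_ssrs:
            if not is_primitive(motif):
                raise ValueError(f"planted motif {motif!r} is not primitive")
            if count < 2:
                raise ValueError("planted repeat count must be >= 2")
            if not (0 <= sc_idx < self.n_scaffolds):
                raise ValueError(f"scaffold index {sc_idx} out of range")
            end = start + len(motif) * count - 1
            if start < 51 or end > lo - 50:
                raise ValueError(
                    f"planted SSR at scaffold {sc_idx}:{start} must sit >= 50 bp "
                    "from both ends of the shortest scaffold"
                )
            for s, e in by_scaffold.get(sc_idx, []):
                if not (end < s or start > e):
                    raise ValueError(f"planted SSRs overlap on scaffold {sc_idx}")
            by_scaffold.setdefault(sc_idx, []).append((start, end))


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Mixture k-mer spectrum of a diploid genome."""

    genome_size: int
    coverage: float
    het_rate: float = 0.0
    repeat_fraction: float = 0.0
    error_kmer_mass: float = 0.0
    k: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size < 1:
            raise ValueError("genome_size must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for name in ("het_rate", "repeat_fraction", "error_kmer_mass"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.k not in (15, 17, 19, 21):
            raise ValueError("k must be one of 15, 17, 19, 21")


@dataclass(frozen=True)
class PopSimSpec:
    """Multi-population diploid SSR genotype panel."""

    n_pops: int = 2
    n_per_pop: tuple[int, ...] = (10, 5)
    n_loci: int = 36
    alleles_per_locus: tuple[int, int] = (2, 7)
    divergence: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("need at least one population")
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        if any(n < 2 for n in self.n_per_pop):
            raise ValueError("need at least 2 individuals per population")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        lo, hi = self.alleles_per_locus
        if not (1 <= lo <= hi):
            raise ValueError("invalid alleles_per_locus range")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def simulate_scaffolds(
    spec: GenomeSimSpec,
) -> tuple[list[SequenceRecord], list[SSRLocus]]:
    """Scaffolds plus the truth table of planted SSR loci.

    Background residues are i.i.d. with P(G) + P(C) = ``gc_target``; the
    background of each scaffold is redrawn (rejection sampling from the same
    seeded stream) until it contains no unplanned run passing the default
    mining thresholds and does not extend any planted locus, so the truth
    table is exactly what a perfect miner should report.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    planted_by_scaffold: dict[int, list[tuple[str, int, int]]] = {}
    for motif, count, sc_idx, start in spec.planted_ssrs:
        planted_by_scaffold.setdefault(sc_idx, []).append((motif, count, start))
    records: list[SequenceRecord] = []
    truth: list[SSRLocus] = []
    for idx in range(spec.n_scaffolds):
        length = int(rng.integers(lo, hi + 1))
        planted = sorted(planted_by_scaffold.get(idx, []), key=lambda p: p[2])
        name = f"scaffold_{idx + 1}"
        for _attempt in range(200):
            seq = _random_background(rng, length, spec.gc_target)
            for motif, count, start in planted:
                insert = motif * count
                seq = seq[: start - 1] + insert + seq[start - 1 + len(insert) :]
            if _scaffold_is_clean(seq, planted):
                break
        else:
            raise RuntimeError(
                f"could not draw a clean background for scaffold {idx} "
                "in 200 attempts"
            )
        records.append(SequenceRecord(id=name, residues=seq))
        for motif, count, start in planted:
            truth.append(
                SSRLocus(
                    scaffold_id=name,
                    start=start,
                    end=start + len(motif) * count - 1,
                    period=len(motif),
                    motif=motif,
                    repeat_count=count,
                )
            )
    truth.sort(key=lambda l: (l.scaffold_id, l.start))
    return records, truth


def _scaffold_is_clean(
    seq: str, planted: Sequence[tuple[str, int, int]]
) -> bool:
    """True when the minable locus set of the finished scaffold is exactly
    the planted loci that pass the default thresholds.

    A full scan of the assembled sequence catches both unplanned background
    runs and junction artefacts (flanking bases that would extend a planted
    run and shift its maximal coordinates).  Partial-unit continuations at
    either flank are rejected too, so planted loci are maximal runs of whole
    units on both strands.
    """
    from .ssr_miner import _resolve_overlaps, _scan_segment

    for motif, count, start in planted:
        p = len(motif)
        s0 = start - 1
        e0 = s0 + p * count  # exclusive
        if s0 - 1 >= 0 and seq[s0 - 1] == seq[s0 - 1 + p]:
            return False
        if e0 < len(seq) and seq[e0] == seq[e0 - p]:
            return False
    found = {
        (l.start, l.end, l.period, l.motif)
        for l in _resolve_overlaps(_scan_segment(seq, 0, "x", DEFAULT_MIN_REPEATS))
    }
    expected = set()
    for motif, count, start in planted:
        if count >= DEFAULT_MIN_REPEATS.get(len(motif), 10 ** 9):
            expected.add((start, start + len(motif) * count - 1, len(motif), motif))
    return found == expected


def simulate_kmer_histogram(spec: SpectrumSimSpec) -> KmerHistogram:
    """Mixture spectrum: error + heterozygous + homozygous + repeat components.

    Unique (non-repeat) genome positions split into heterozygous k-mers
    (fraction f_het = 1 - (1 - het_rate)^k, two variants each at depth
    ~ Poisson(coverage/2)) and homozygous ones (~ Poisson(coverage)).  The
    repeat fraction of positions collapses into families of copy number
    m in {2, 4, 8} (observation mass split 0.2/0.4/0.4) with one distinct
    k-mer per family at ~ Poisson(m * coverage).  Error k-mers add
    ``error_kmer_mass`` of the total observation mass at depths 1-2.
    Depth counts are drawn multinomially, so the realized histogram
    conserves the expected mass up to sampling noise.
    """
    rng = np.random.default_rng(spec.seed)
    g, lam, k = spec.genome_size, spec.coverage, spec.k
    f_het = 1.0 - (1.0 - spec.het_rate) ** k
    unique = g * (1.0 - spec.repeat_fraction)
    components: list[tuple[float, float]] = []  # (n_distinct, poisson mean)
    if unique > 0:
        if f_het > 0:
            components.append((2.0 * unique * f_het, lam / 2.0))
        components.append((unique * (1.0 - f_het), lam))
    repeat_mass = spec.repeat_fraction * g * lam
    for m, w in REPEAT_COPY_WEIGHTS.items():
        n_distinct = w * repeat_mass / (m * lam)
        if n_distinct > 0:
            components.append((n_distinct, m * lam))
    dmax = int(np.ceil(8 * lam + 10 * np.sqrt(8 * lam) + 20))
    depths = np.arange(0, dmax + 1)
    counts = np.zeros(dmax + 1, dtype=np.int64)
    for n_distinct, mu in components:
        pmf = poisson.pmf(depths, mu)
        pmf = np.append(pmf, max(0.0, 1.0 - pmf.sum()))
        drawn = rng.multinomial(int(round(n_distinct)), pmf / pmf.sum())
        counts += drawn[: dmax + 1]
    hist: dict[int, int] = {
        int(d): int(c) for d, c in zip(depths[1:], counts[1:]) if c > 0
    }
    if spec.error_kmer_mass > 0:
        genomic_mass = lam * g
        err_mass = spec.error_kmer_mass / (1.0 - spec.error_kmer_mass) * genomic_mass
        hist[1] = hist.get(1, 0) + int(round(0.8 * err_mass))
        hist[2] = hist.get(2, 0) + int(round(0.1 * err_mass))
    if not hist:
        raise ValueError("simulated spectrum is empty")
    return KmerHistogram(k=k, counts=hist)


def simulate_genotypes(
    spec: PopSimSpec,
) -> tuple[GenotypeMatrix, list[dict[int, np.ndarray]], dict[str, int]]:
    """Genotype matrix, per-locus truth frequencies, and population labels.

    Per locus a shared ancestral frequency vector is drawn (flat Dirichlet);
    each population's frequencies are a Balding-Nichols perturbation with
    concentration (1 - divergence)/divergence, so divergence 0 reproduces the
    ancestral frequencies exactly and divergence 1 fixes a random allele per
    population.  Individuals are Hardy-Weinberg draws; calls are masked
    missing at ``missing_rate``.  Allele labels are fragment sizes in bp.

    Returns ``(matrix, truth, labels)`` where ``truth[locus_index]`` maps
    population index -> allele frequency vector (with the ancestral vector
    under key -1) and ``labels`` maps individual id -> population index.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.alleles_per_locus
    individuals: list[str] = []
    labels: dict[str, int] = {}
    for p in range(spec.n_pops):
        for i in range(spec.n_per_pop[p]):
            ind = f"P{p + 1}_{i + 1:02d}"
            individuals.append(ind)
            labels[ind] = p
    loci = [f"SSR{j + 1:03d}" for j in range(spec.n_loci)]
    calls: dict[tuple[str, str], Optional[tuple[int, int]]] = {}
    truth: list[dict[int, np.ndarray]] = []
    for j, locus in enumerate(loci):
        n_alleles = int(rng.integers(lo, hi + 1))
        # allele labels: fragment sizes stepping by a dinucleotide unit
        base = int(rng.integers(100, 280))
        sizes = [base + 2 * a for a in range(n_alleles)]
        ancestral = rng.dirichlet(np.ones(n_alleles))
        locus_truth: dict[int, np.ndarray] = {-1: ancestral}
        for p in range(spec.n_pops):
            if spec.divergence == 0.0:
                freqs = ancestral.copy()
            elif spec.divergence == 1.0:
                freqs = np.zeros(n_alleles)
                freqs[rng.choice(n_alleles, p=ancestral)] = 1.0
            else:
                conc = (1.0 - spec.divergence) / spec.divergence
                # floor the Dirichlet concentration: near-zero shapes make
                # the gamma sampler return an all-zero vector
                alpha = np.maximum(conc * ancestral, 1e-4)
                freqs = rng.dirichlet(alpha)
                if not np.all(np.isfinite(freqs)) or freqs.sum() <= 0:
                    freqs = ancestral.copy()
            locus_truth[p] = freqs
        truth.append(locus_truth)
        for ind in individuals:
            freqs = locus_truth[labels[ind]]
            if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                calls[(ind, locus)] = MISSING
                continue
            a, b = rng.choice(len(sizes), size=2, p=freqs)
            pair = (sizes[int(a)], sizes[int(b)])
            calls[(ind, locus)] = (min(pair), max(pair))
    matrix = GenotypeMatrix(individuals=individuals, loci=loci, calls=calls)
    return matrix, truth, labels
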