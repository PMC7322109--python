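# Methods

`ssrsurvey` implements the analysis chain of a low-coverage genome survey of
a non-model diploid: profile the genome from a k-mer spectrum, summarize a
draft assembly, mine perfect microsatellites (SSRs), design PCR primers
around them, and evaluate the resulting markers on a panel of individuals
(diversity statistics and UPGMA clustering). This note records the models,
the defaults and why they were chosen, and what the synthetic data do and do
not establish.

## K-mer spectrum model

The spectrum of a read set is the histogram `n_d` = number of distinct
k-mers (default k = 17) observed exactly `d` times. For a diploid genome of
size `G` sequenced at coverage `λ`:

* **Genome size.** The unique-genome peak sits at depth ≈ λ, and
  `G ≈ (Σ_d d·n_d) / peak_depth`. The *revised* size additionally removes
  the observation mass below the error cutoff from the numerator, so it is
  the estimate to use whenever an error component is present.
* **Error cutoff.** Erroneous k-mers concentrate at depth 1–2. The cutoff is
  the first local minimum of `n_d` scanning upward over the depths actually
  observed. At desk scale the error tail and the genomic peak are often
  separated by a run of zero-count depths; the valley is then placed
  immediately after the error tail. A spectrum that only ever decreases from
  depth 1 has no genomic peak and is rejected as uninformative; a spectrum
  whose support starts at its own peak (above depth 1) has no error
  component and gets a cutoff at the start of its support.
* **Peak disambiguation.** A heterozygous genome shows a second peak at λ/2
  (k-mers overlapping a heterozygous site split into two half-depth
  variants), which can be *taller* than the homozygous peak. Among local
  maxima at or above the cutoff with height ≥ 10 % of the tallest, if the
  tallest maximum `T` is accompanied by a maximum `q ≈ 2T` (within
  `max(2, 0.1 q)`) whose height reaches at least 50 % of `T`'s, `q` is taken
  as the homozygous peak. The 50 % height guard is this package's choice: a
  repeat shoulder at 2λ also sits at twice the main peak but is much
  shorter than it, while a genuine homozygous peak beside a het peak is of
  comparable height. The heuristic can always be bypassed with an explicit
  peak depth.
* **Heterozygosity.** A non-negative least-squares fit of two Poisson
  components (means `peak/2` and `peak`) to `n_d` on
  `cutoff ≤ d ≤ 2·peak` yields distinct-k-mer counts `A` (half depth) and
  `B` (full depth). Since each heterozygous k-mer contributes two variants,
  the heterozygous fraction of k-mers is `f_het = (A/2)/(A/2 + B)`, and the
  per-base rate follows from the independence approximation
  `f_het = 1 − (1 − r)^k`. Weights below 1e-4 are reported as 0. Least
  squares (not maximum likelihood) is deliberate: it is robust at desk
  scale and no inferential claims are attached to the fit.
* **Repeat fraction.** Share of non-erroneous observation mass at depth
  greater than `multiplier × peak` (default multiplier 2, exposed as a
  flag). This is a simple tail statistic, not a repeat-landscape model; a
  2-copy repeat family loses roughly the half of its Poisson(2λ) mass that
  falls below the threshold, so the estimate is conservative by design.

## Synthetic spectra

`simulate_kmer_histogram` assembles a spectrum from the same components the
estimators assume: heterozygous k-mers (`2·U·f_het` distinct at
Poisson(λ/2), where `U` is the unique-genome size), homozygous unique k-mers
(`U·(1−f_het)` at Poisson(λ)), repeat families of copy number {2, 4, 8}
(one distinct k-mer per family at Poisson(m·λ)), and an error component
placed at depths 1–2 holding a chosen fraction of the total observation
mass. Repeat observation mass is split 0.2/0.4/0.4 over the three copy
numbers — in a highly repetitive genome most repetitive mass belongs to
deep families, which is also what makes the fat tail visibly separate from
the main peak. Depth counts are multinomial draws from the exact Poisson
mass function, so the realized spectrum conserves expected mass to well
under 1 % for genomes ≥ 1 Mb. Depth components are Poisson, not negative
binomial: the simplest model sufficient for recovery testing;
overdispersion is an extension hook.

What these simulations do **not** capture: GC-biased coverage, a continuous
repeat-copy-number landscape, correlated errors, and ploidy > 2. Passing
recovery tests therefore demonstrates internal consistency of the
estimators under the stated model, not calibration on real read sets. Tests
run at G of 1–10 Mb and 20 replicate spectra, sizes at which every
component's sampling noise is far below the tested tolerances.

## SSR mining

A locus is a maximal run of a primitive motif (period 1–6) repeated at
least 10/6/5/5/5/5 times (mono- through hexanucleotide), mined from
scaffolds of length ≥ 1000 bp (both thresholds exposed). Runs containing N
are broken at the N; partial trailing units are trimmed, so a locus always
spans `period × repeats` bases (a `(AG)6` followed by a lone `A` is still 6
repeats); primitivity guarantees a run is reported once, at its smallest
period. Runs of different periods that merely share boundary bases are
resolved greedily — longest run first, then smaller period, then leftmost —
so reported loci never overlap. Only perfect SSRs are reported; compound
SSRs (interrupted repeats within a joining distance) are out of scope
because simple motifs are what the downstream marker tables use.

The canonical class of a motif is `X/Y` where `X` is the lexicographic
minimum over all rotations of the motif and of its reverse complement and
`Y = revcomp(X)` (so `TAT`, `ATA`, `AAT`, `ATT`, `TTA`, `TAA` are all
`AAT/ATT`). Repeat-count summary bins are {≤5, 6, 7, 8, 9, 10, 11–20, >20},
kept disjoint. The mean inter-locus distance is scanned length / locus
count, reported in kb to 2 decimals.

`simulate_scaffolds` plants chosen SSRs into i.i.d. background of a target
GC content and redraws each scaffold's background (from the same seeded
stream) until the scaffold's minable locus set is exactly the planted set
— this also rejects flanking bases that would extend a planted run by a
full or partial unit and thereby shift its maximal coordinates on either
strand. The truth table is therefore an exact oracle for the miner, and an
independent regex enumeration cross-checks both.

## Primer design

The design space is a Primer-3-style constraint envelope: product 100–300
bp, primer 18–27 nt, GC 40–70 %, Tm 57–63 °C, with optima 200 bp / 20 nt /
50 % / 60 °C. All (forward, reverse) window pairs flanking the locus are
enumerated exhaustively, scored by unweighted L1 deviation from the optima
and returned best-first (ties: leftmost forward start, then shortest
product). Melting temperatures default to SantaLucia-1998 unified
nearest-neighbor thermodynamics at 50 mM monovalent salt and 0.25 µM total
strand; the Wallace 2(A+T) + 4(G+C) rule is available for hand-checkable
work. Primer 3's full penalty model (self-complementarity, end stability,
hairpin ΔG) is intentionally out of scope; a simple
reverse-complement-substring self-dimer screen is available as an optional
filter. Redundancy removal collapses pairs with identical
(forward, reverse) sequences, keeping the first in locus order — sequence
identity is the only defensible criterion without the original scaffold
set.

## Marker statistics

Per locus over any subset of individuals, with missing calls excluded
listwise: `Na` = distinct alleles, `Ho` = heterozygous / typed,
`He_biased = 1 − Σ f_i²` over allele frequencies (each diploid call
contributes two observations), `He_unbiased = 2n/(2n−1) · He_biased`, and
`PIC = 1 − Σ f_i²` — the gene-diversity form, not the Botstein double-sum
correction, because that is the form marker panels of this kind print. He
defaults to the sample-size-corrected value (the POPGENE convention, and
the reason published tables can show He > PIC at small n), with a flag to
switch. Botstein classes: PIC < 0.25 low, > 0.5 high, boundary values
moderate (strict published inequalities leave 0.25 and 0.5 unassigned;
moderate is the conservative assignment). Panel summaries are unweighted
means over loci.

`simulate_genotypes` draws, per locus, a flat-Dirichlet ancestral frequency
vector; each population's frequencies are a Balding–Nichols perturbation
with concentration `(1 − F)/F` for divergence `F` (exactly ancestral at
F = 0, fixed random allele at F = 1); individuals are Hardy–Weinberg draws;
calls are masked missing at a chosen rate. Defaults mirror a two-species
screening panel: 10 + 5 individuals, 36 loci, 2–7 alleles per locus.

## Clustering

Genotypes are expanded into a binary band matrix (one column per observed
locus/allele). Similarity uses simple matching by default — the common
choice for band data in NTSYS-style analyses; Dice and Jaccard are
selectable, and since the coefficient behind any given published dendrogram
is usually unstated, no printed similarity range is treated as a
reproduction target. Columns from loci where either individual is missing
are deleted pairwise. UPGMA runs on `d = 1 − GSC` with size-weighted
average linkage; a merge at distance `d` sits at height `d/2`; ties break
deterministically by the lexicographically smallest pair of cluster
representative ids, and children are ordered by representative, so runs are
exactly reproducible under input permutation (up to tie conventions).
Cutting at similarity `s` cuts the tree at height `(1 − s)/2`. Identical
individuals always merge first at height 0.

## Numerical and interface conventions

Coordinates are 1-based inclusive everywhere; sequences are uppercased on
read and restricted to {A, C, G, T, N} (IUPAC ambiguity codes are rejected
so malformed inputs fail fast); FASTQ is Phred+33; genotype CSV uses
fragment sizes in bp as allele labels with `a/b`, homozygote shorthand
`a`, and `NA`; `.gz` inputs are detected by suffix. The assembly GC filter
"longer than 500 bp" is implemented as ≥ 500 (the boundary is ambiguous in
common usage; the threshold is exposed). All generators are pure functions
of their spec, seed included.

## Known limitations

* The error-cutoff and peak heuristics assume a roughly unimodal genomic
  component; pathological multi-modal spectra need the manual peak
  override.
* The repeat-fraction tail statistic undercounts 2-copy families (see
  above); agreement with a survey's printed repeat percentage is expected
  only qualitatively.
* Primer Tm ignores divalent cations and dNTPs; constraints are evaluated
  per primer, not per pair (no cross-dimer thermodynamics).
* The k-mer counter is a plain dictionary tally intended for toy-scale
  inputs (≤ a few Mb), not a production counter.
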