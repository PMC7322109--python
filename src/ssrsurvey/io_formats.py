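"""Readers and writers for every external representation the pipeline touches.

Formats: FASTA and FASTQ (plain or gzipped, detected by a ``.gz`` suffix;
FASTQ qualities are Phred+33), two-column k-mer histogram TSV
(``depth<TAB>count``), genotype CSV (individuals x loci, allele-size pairs),
per-locus SSR / primer TSV tables, and Newick trees.

Coordinates in all tabular output are 1-based inclusive.  The residue
alphabet is restricted to ``{A, C, G, T, N}``; IUPAC ambiguity codes are
rejected so malformed input fails fast.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "QualitySummary",
    "GenotypeMatrix",
    "MISSING",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "quality_summary",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_kmer_histogram",
    "write_kmer_histogram",
    "write_newick",
    "write_ssr_table",
    "write_primer_table",
]

VALID_RESIDUES = frozenset("ACGTN")

#: Sentinel for an untyped genotype call.
MISSING = None


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """One FASTA/FASTQ entry.

    ``qualities`` (per-base Phred scores) are present iff the record was read
    from FASTQ.
    """

    id: str
    residues: str
    description: str = ""
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues, start=1) if c in bad
            )
            raise FormatError(
                f"record {self.id!r}: illegal residue {self.residues[pos - 1]!r} "
                f"at position {pos}"
            )
        if self.qualities is not None:
            if len(self.qualities) != len(self.residues):
                raise ValueError(
                    f"record {self.id!r}: {len(self.qualities)} quality scores "
                    f"for {len(self.residues)} residues"
                )
            if any(q < 0 for q in self.qualities):
                raise ValueError(f"record {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class QualitySummary:
    """Read-set quality statistics (Q20/Q30/GC/error-rate, all percentages)."""

    n_reads: int
    n_bases: int
    q20_pct: float
    q30_pct: float
    gc_pct: float
    error_rate_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q30_pct <= self.q20_pct <= 100.0):
            raise ValueError("require 0 <= Q30% <= Q20% <= 100")
        if not (0.0 <= self.gc_pct <= 100.0):
            raise ValueError("GC% outside [0, 100]")
        if self.error_rate_pct < 0.0:
            raise ValueError("negative error rate")


@dataclass
class GenotypeMatrix:
    """Individuals x loci co-dominant calls, alleles labelled by fragment size (bp).

    Each call is an unordered pair of positive-integer allele labels, stored
    sorted, or :data:`MISSING`.
    """

    individuals: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], Optional[tuple[int, int]]]

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        for key, call in self.calls.items():
            if call is not MISSING:
                a, b = call
                if a <= 0 or b <= 0:
                    raise ValueError(f"non-positive allele label at {key}")
                if a > b:
                    self.calls[key] = (b, a)

    def call(self, individual: str, locus: str) -> Optional[tuple[int, int]]:
        return self.calls.get((individual, locus), MISSING)

    def is_missing(self, individual: str, locus: str) -> bool:
        return self.call(individual, locus) is MISSING


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into validated, uppercased records."""
    with _open_text(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise FormatError(f"{path}: no records (empty file)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: sequence line before any FASTA header")
    with _open_text(path) as fh:
        records = [
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=rec.description[len(rec.id) :].strip(),
            )
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        records = [
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=rec.description[len(rec.id) :].strip(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]
    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n")
            fh.write("".join(chr(q + 33) for q in rec.qualities) + "\n")


def quality_summary(records: Sequence[SequenceRecord]) -> QualitySummary:
    """Q20/Q30/GC/error-rate summary of a FASTQ read set.

    Q20/Q30 are the percentage of bases with Phred >= 20/30; GC% is computed
    over called (non-N) bases; the error rate is the mean per-base error
    probability ``10^(-Q/10)``, as a percentage.
    """
    if not records:
        raise ValueError("no reads")
    for rec in records:
        if rec.qualities is None:
            raise ValueError(f"record {rec.id!r} carries no qualities")
    quals = np.concatenate([np.asarray(r.qualities) for r in records])
    n_bases = quals.size
    seq = "".join(r.residues for r in records)
    gc = seq.count("G") + seq.count("C")
    acgt = n_bases - seq.count("N")
    if acgt == 0:
        raise ValueError("no called bases")
    return QualitySummary(
        n_reads=len(records),
        n_bases=int(n_bases),
        q20_pct=100.0 * float(np.mean(quals >= 20)),
        q30_pct=100.0 * float(np.mean(quals >= 30)),
        gc_pct=100.0 * gc / acgt,
        error_rate_pct=100.0 * float(np.mean(10.0 ** (-quals / 10.0))),
    )


def _parse_call(cell: str, where: str) -> Optional[tuple[int, int]]:
    cell = cell.strip()
    if cell in ("NA", "", "-", "–"):
        return MISSING
    parts = cell.split("/")
    if len(parts) == 1:
        parts = [parts[0], parts[0]]  # homozygote shorthand "a" -> a/a
    if len(parts) != 2:
        raise FormatError(f"{where}: malformed call {cell!r}")
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise FormatError(f"{where}: non-numeric allele label in {cell!r}") from exc
    if a <= 0 or b <= 0:
        raise FormatError(f"{where}: allele labels must be positive, got {cell!r}")
    return (min(a, b), max(a, b))


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read a genotype CSV: header of locus names, first column individual id.

    Cells are ``a/b`` (allele sizes in bp), ``a`` (homozygote shorthand), or
    ``NA``.  Pairs are unordered: ``231/235`` equals ``235/231``.
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty genotype file")
    header = lines[0].split(",")
    loci = [h.strip() for h in header[1:]]
    individuals: list[str] = []
    calls: dict[tuple[str, str], Optional[tuple[int, int]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != len(loci) + 1:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                f"expected {len(loci) + 1})"
            )
        ind = cells[0].strip()
        individuals.append(ind)
        for locus, cell in zip(loci, cells[1:]):
            calls[(ind, locus)] = _parse_call(cell, f"{path}:{lineno}")
    return GenotypeMatrix(individuals=individuals, loci=loci, calls=calls)


def write_genotype_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("individual," + ",".join(matrix.loci) + "\n")
        for ind in matrix.individuals:
            row = [ind]
            for locus in matrix.loci:
                call = matrix.call(ind, locus)
                row.append("NA" if call is MISSING else f"{call[0]}/{call[1]}")
            fh.write(",".join(row) + "\n")


def read_kmer_histogram(path: str | Path):
    """Read a two-column histogram TSV (depth, distinct-k-mer count), k from ``# k=``.

    Depths must be strictly increasing positive integers; counts non-negative.
    """
    from .kmer_profile import KmerHistogram

    k = 17
    counts: dict[int, int] = {}
    last_depth = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "k=" in line:
                    k = int(line.split("k=")[1].split()[0])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                depth, count = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if depth in counts or depth <= last_depth:
                raise FormatError(f"{path}:{lineno}: depths must be strictly increasing")
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            counts[depth] = count
            last_depth = depth
    if not counts:
        raise FormatError(f"{path}: empty histogram")
    return KmerHistogram(k=k, counts=counts)


def write_kmer_histogram(hist, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# k={hist.k}\n")
        for depth in sorted(hist.counts):
            fh.write(f"{depth}\t{hist.counts[depth]}\n")


def write_newick(tree, path: str | Path) -> None:
    """Serialize a :class:`~ssrsurvey.cluster.Dendrogram` as Newick with branch lengths."""
    with _open_text(path, "wt") as fh:
        fh.write(tree.to_newick() + "\n")


def write_ssr_table(loci, path: str | Path) -> None:
    """Per-locus SSR TSV; coordinates 1-based inclusive."""
    with _open_text(path, "wt") as fh:
        fh.write("# SSR loci; start/end are 1-based inclusive\n")
        fh.write("scaffold\tstart\tend\tperiod\tmotif\tclass\trepeats\n")
        for loc in loci:
            fh.write(
                f"{loc.scaffold_id}\t{loc.start}\t{loc.end}\t{loc.period}\t"
                f"{loc.motif}\t{loc.canonical_class}\t{loc.repeat_count}\n"
            )


def read_ssr_table(path: str | Path):
    from .ssr_miner import SSRLocus

    loci = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("scaffold\t"):
                continue
            sc, start, end, period, motif, _cls, reps = line.split("\t")
            loci.append(
                SSRLocus(
                    scaffold_id=sc,
                    start=int(start),
                    end=int(end),
                    period=int(period),
                    motif=motif,
                    repeat_count=int(reps),
                )
            )
    return loci


def write_primer_table(pairs, path: str | Path) -> None:
    """Primer-pair TSV; template coordinates 1-based inclusive."""
    with _open_text(path, "wt") as fh:
        fh.write("# primer pairs; fwd_start/rev_end are 1-based inclusive template coords\n")
        fh.write(
            "locus\tfwd_seq\trev_seq\tfwd_start\trev_end\tproduct_len\t"
            "fwd_tm\trev_tm\tfwd_gc\trev_gc\tscore\n"
        )
        for p in pairs:
            fh.write(
                f"{p.locus_id}\t{p.fwd_seq}\t{p.rev_seq}\t{p.fwd_start}\t{p.rev_end}\t"
                f"{p.product_len}\t{p.fwd_tm:.2f}\t{p.rev_tm:.2f}\t"
                f"{p.fwd_gc:.2f}\t{p.rev_gc:.2f}\t{p.score:.3f}\n"
            )
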