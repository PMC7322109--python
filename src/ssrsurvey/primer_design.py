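"""Constraint-based PCR primer design for SSR loci.

Re-implements a Primer-3-style search as an exhaustive enumeration over the
constraint envelope: product length 100-300 bp, primer length 18-27 bp, GC
40-70 %, melting temperature 57-63 C, with scoring by summed absolute
deviation from the optima (product 200 bp, length 20 bp, GC 50 %, Tm 60 C).
Melting temperatures use SantaLucia-1998 unified nearest-neighbor
thermodynamics at 50 mM monovalent salt and 0.25 uM total strand by default;
the Wallace 2+4 rule is available for hand-checkable work.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .io_formats import SequenceRecord
from .ssr_miner import SSRLocus

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "melting_temp",
    "gc_percent",
    "design_for_locus",
    "dedupe_pairs",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerConstraints:
    """The design envelope plus scoring optima."""

    product_len: tuple[int, int] = (100, 300)
    primer_len: tuple[int, int] = (18, 27)
    gc: tuple[float, float] = (40.0, 70.0)
    tm: tuple[float, float] = (57.0, 63.0)
    product_opt: float = 200.0
    primer_len_opt: float = 20.0
    gc_opt: float = 50.0
    tm_opt: float = 60.0

    def __post_init__(self) -> None:
        for lo, hi, opt, name in (
            (*self.product_len, self.product_opt, "product_len"),
            (*self.primer_len, self.primer_len_opt, "primer_len"),
            (*self.gc, self.gc_opt, "gc"),
            (*self.tm, self.tm_opt, "tm"),
        ):
            if lo > hi:
                raise ValueError(f"{name}: empty interval [{lo}, {hi}]")
            if not (lo <= opt <= hi):
                raise ValueError(f"{name}: optimum {opt} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse pair flanking one SSR locus.

    ``fwd_start``/``rev_end`` are 1-based inclusive template coordinates;
    ``rev_seq`` is the reverse complement of the template window.
    """

    locus_id: str
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_end: int
    product_len: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    score: float

    def __post_init__(self) -> None:
        if self.product_len != self.rev_end - self.fwd_start + 1:
            raise ValueError("product length inconsistent with coordinates")


def gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str, method: str = "nearest_neighbor") -> float:
    """Oligo melting temperature in C.

    ``wallace``: 2*(A+T) + 4*(G+C).  ``nearest_neighbor``: SantaLucia 1998
    unified parameters, 50 mM Na+, 0.25 uM total strand concentration.
    """
    if len(seq) < 8:
        raise ValueError("primer shorter than 8 nt")
    if set(seq) - set("ACGT"):
        raise ValueError(f"primer contains non-ACGT characters: {seq!r}")
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        return float(2 * at + 4 * (len(seq) - at))
    if method == "nearest_neighbor":
        return float(
            _mt.Tm_NN(
                seq,
                nn_table=_mt.DNA_NN3,
                Na=50,
                dnac1=125,
                dnac2=125,
                saltcorr=5,
            )
        )
    raise ValueError(f"unknown Tm method {method!r}")


def _window_candidates(
    template: str,
    start_lo: int,
    start_hi: int,
    end_cap: int,
    constraints: PrimerConstraints,
    tm_method: str,
) -> list[tuple[int, int, str, float, float]]:
    """(start0, end0, seq, gc, tm) for every constraint-passing window with
    0-based start in [start_lo, start_hi] and end <= end_cap."""
    out = []
    len_lo, len_hi = constraints.primer_len
    for s in range(max(0, start_lo), start_hi + 1):
        for length in range(len_lo, len_hi + 1):
            e = s + length - 1
            if e > end_cap:
                break
            seq = template[s : e + 1]
            if "N" in seq:
                continue
            gc = gc_percent(seq)
            if not (constraints.gc[0] <= gc <= constraints.gc[1]):
                continue
            tm = melting_temp(seq, method=tm_method)
            if not (constraints.tm[0] <= tm <= constraints.tm[1]):
                continue
            out.append((s, e, seq, gc, tm))
    return out


def design_for_locus(
    record: SequenceRecord,
    locus: SSRLocus,
    constraints: Optional[PrimerConstraints] = None,
    max_returned: int = 1,
    tm_method: str = "nearest_neighbor",
) -> list[PrimerPair]:
    """Best-scoring primer pairs spanning one locus.

    Exhaustively enumerates all (forward, reverse) window pairs that satisfy
    every constraint, with the forward window entirely upstream of the locus
    and the reverse window entirely downstream.  Pairs are scored by summed
    absolute deviation from the optima (unit weights); ties break by leftmost
    forward start, then shortest product.  Returns up to ``max_returned``
    pairs; an empty list when no pair satisfies the constraints.
    """
    if constraints is None:
        constraints = PrimerConstraints()
    template = record.residues
    if locus.scaffold_id != record.id:
        raise ValueError("locus does not belong to this record")
    if not (1 <= locus.start <= locus.end <= len(template)):
        raise ValueError("locus does not lie on the record")
    prod_lo, prod_hi = constraints.product_len
    loc_s0, loc_e0 = locus.start - 1, locus.end - 1  # 0-based
    # forward windows end strictly before the locus; bound the search window
    # by the maximum product length
    fwd = _window_candidates(
        template,
        start_lo=loc_e0 - prod_hi + 1 + constraints.primer_len[0],
        start_hi=loc_s0 - constraints.primer_len[0],
        end_cap=loc_s0 - 1,
        constraints=constraints,
        tm_method=tm_method,
    )
    rev = _window_candidates(
        template,
        start_lo=loc_e0 + 1,
        start_hi=min(len(template), loc_s0 + prod_hi) - constraints.primer_len[0],
        end_cap=min(len(template) - 1, loc_s0 - 1 + prod_hi + constraints.primer_len[1]),
        constraints=constraints,
        tm_method=tm_method,
    )
    rev = [w for w in rev if w[0] >= loc_e0 + 1]
    rev.sort(key=lambda w: w[1])
    rev_ends = [w[1] for w in rev]
    scored: list[tuple[float, int, int, PrimerPair]] = []
    for fs, fe, fseq, fgc, ftm in fwd:
        lo_i = bisect_left(rev_ends, fs + prod_lo - 1)
        hi_i = bisect_right(rev_ends, fs + prod_hi - 1)
        for rs, re_, rwin, rgc, rtm in rev[lo_i:hi_i]:
            product = re_ - fs + 1
            score = (
                abs(product - constraints.product_opt)
                + abs(len(fseq) - constraints.primer_len_opt)
                + abs(len(rwin) - constraints.primer_len_opt)
                + abs(fgc - constraints.gc_opt)
                + abs(rgc - constraints.gc_opt)
                + abs(ftm - constraints.tm_opt)
                + abs(rtm - constraints.tm_opt)
            )
            pair = PrimerPair(
                locus_id=f"{locus.scaffold_id}:{locus.start}-{locus.end}",
                fwd_seq=fseq,
                rev_seq=_revcomp(rwin),
                fwd_start=fs + 1,
                rev_end=re_ + 1,
                product_len=product,
                fwd_tm=ftm,
                rev_tm=rtm,
                fwd_gc=fgc,
                rev_gc=rgc,
                score=score,
            )
            scored.append((score, fs, product, pair))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return [t[3] for t in scored[:max_returned]]


def has_selfdimer(pair: PrimerPair, seed_len: int = 8) -> bool:
    """Simple screen: either primer contains the reverse complement of a
    ``seed_len``-mer of the other (or of itself)."""
    seqs = (pair.fwd_seq, pair.rev_seq)
    for a in seqs:
        for b in seqs:
            rc = _revcomp(b)
            for i in range(len(rc) - seed_len + 1):
                if rc[i : i + seed_len] in a:
                    return True
    return False


def dedupe_pairs(pairs: Sequence[PrimerPair]) -> list[PrimerPair]:
    """Collapse pairs with identical (fwd_seq, rev_seq), keeping the first."""
    seen: set[tuple[str, str]] = set()
    out: list[PrimerPair] = []
    for p in pairs:
        key = (p.fwd_seq, p.rev_seq)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out
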