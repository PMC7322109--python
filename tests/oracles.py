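"""Independent oracles used by the test suite.

Each oracle re-derives a result by a different route than the implementation
it checks: regex enumeration for SSR mining, scipy average-linkage for UPGMA,
a literal SantaLucia-1998 table walk for nearest-neighbor Tm, and O(n^2)
window enumeration for primer search.
"""

from __future__ import annotations

import math
import re

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % p == 0 and motif == motif[:p] * (n // p) for p in range(1, n)
    )


def regex_ssr_oracle(records, min_repeats, min_scaffold_len):
    """Brute-force SSR mining by lookahead regex over every period and start.

    Returns the same locus keys as the miner: (scaffold, start, end, period,
    motif) with 1-based inclusive coordinates, after applying the shared
    reporting policy (primitive motifs, whole-unit trimming, left-maximality,
    longest-run-first overlap resolution).
    """
    out = []
    for rec in records:
        seq = rec.residues
        if len(seq) < min_scaffold_len:
            continue
        cands = []
        offset = 0
        for seg in seq.split("N"):
            for period, thr in min_repeats.items():
                pat = re.compile(r"(?=((\w{%d})\2{%d,}))" % (period, thr - 1))
                for m in pat.finditer(seg):
                    s = m.start()
                    if s >= 1 and seg[s - 1] == seg[s - 1 + period]:
                        continue  # not left-maximal for this period
                    unit = m.group(2)
                    if not _primitive(unit):
                        continue
                    count = len(m.group(1)) // period
                    cands.append(
                        (offset + s + 1, offset + s + count * period, period, unit)
                    )
            offset += len(seg) + 1
        cands.sort(key=lambda c: (-(c[1] - c[0] + 1), c[2], c[0]))
        kept = []
        for c in cands:
            if all(c[1] < k[0] or c[0] > k[1] for k in kept):
                kept.append(c)
        out.extend((rec.id, s, e, p, u) for (s, e, p, u) in kept)
    return set(out)


def scipy_upgma_cophenetic(sim_values: np.ndarray) -> np.ndarray:
    """Condensed cophenetic distance matrix of average-linkage clustering on
    d = 1 - similarity."""
    d = squareform(1.0 - sim_values, checks=False)
    return cophenet(linkage(d, method="average"))


# SantaLucia (1998) unified nearest-neighbor parameters:
# dH kcal/mol, dS cal/(mol K), one entry per distinct stacked pair.
_NN_TABLE = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = str.maketrans("ACGT", "TGCA")


def santalucia_tm_oracle(seq: str, na_molar: float = 0.05, ct_molar: float = 250e-9) -> float:
    """Literal table-walk Tm: unified init terms, entropic salt correction
    0.368 (N-1) ln[Na+], non-self-complementary CT/4 convention."""
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN_TABLE:
            pair = pair.translate(_COMP)[::-1]
        h, s = _NN_TABLE[pair]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    return dh * 1000.0 / (ds + 1.987 * math.log(ct_molar / 4.0)) - 273.15


def brute_force_primer_search(template, locus_start, locus_end, constraints, tm):
    """Enumerate every (fwd, rev) window pair satisfying the constraint
    envelope; return the scored list sorted by (score, fwd_start, product).

    Coordinates 1-based inclusive; ``tm`` is a callable seq -> Tm.
    """
    plo, phi = constraints.product_len
    llo, lhi = constraints.primer_len
    n = len(template)

    def windows(lo0, hi0):
        found = []
        for s in range(lo0, hi0 + 1):
            for length in range(llo, lhi + 1):
                e = s + length - 1
                if e >= n:
                    break
                w = template[s : e + 1]
                if "N" in w:
                    continue
                gc = 100.0 * (w.count("G") + w.count("C")) / len(w)
                if not (constraints.gc[0] <= gc <= constraints.gc[1]):
                    continue
                t = tm(w)
                if not (constraints.tm[0] <= t <= constraints.tm[1]):
                    continue
                found.append((s, e, w, gc, t))
        return found

    fwd = [w for w in windows(0, n - 1) if w[1] < locus_start - 1]
    rev = [w for w in windows(0, n - 1) if w[0] > locus_end - 1]
    scored = []
    for fs, fe, fw, fgc, ftm in fwd:
        for rs, re_, rw, rgc, rtm in rev:
            product = re_ - fs + 1
            if not (plo <= product <= phi):
                continue
            score = (
                abs(product - constraints.product_opt)
                + abs(len(fw) - constraints.primer_len_opt)
                + abs(len(rw) - constraints.primer_len_opt)
                + abs(fgc - constraints.gc_opt)
                + abs(rgc - constraints.gc_opt)
                + abs(ftm - constraints.tm_opt)
                + abs(rtm - constraints.tm_opt)
            )
            scored.append((score, fs + 1, product, fw, rw))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return scored
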