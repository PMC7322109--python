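from itertools import product

import pytest

from oracles import regex_ssr_oracle
from ssrsurvey.io_formats import SequenceRecord
from ssrsurvey.ssr_miner import (
    MotifDistribution,
    canonical_class,
    find_ssrs,
    is_primitive,
    mean_distance_kb,
    share_pct,
    summarize_ssrs,
)
from ssrsurvey.synthetic_data import GenomeSimSpec, simulate_scaffolds

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_COMP)[::-1]


def _single_planted(motif, count, seed=41):
    spec = GenomeSimSpec(
        n_scaffolds=1,
        length_range=(1200, 1200),
        planted_ssrs=((motif, count, 0, 400),),
        seed=seed,
    )
    return simulate_scaffolds(spec)


class TestCanonicalClass:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("TAT", "AAT/ATT"),
            ("T", "A/T"),
            ("A", "A/T"),
            ("AT", "AT/AT"),
            ("CG", "CG/CG"),
            ("GAA", "AAG/CTT"),
            ("AG", "AG/CT"),
            ("TTTA", "AAAT/ATTT"),
        ],
    )
    def test_known_classes(self, motif, expected):
        assert canonical_class(motif) == expected

    def test_non_primitive_rejected(self):
        with pytest.raises(ValueError, match="primitive"):
            canonical_class("ATAT")

    def test_invariant_under_rotation_and_revcomp_exhaustive(self):
        # every primitive motif of period <= 3
        for length in (1, 2, 3):
            for motif in map("".join, product("ACGT", repeat=length)):
                if not is_primitive(motif):
                    continue
                ref = canonical_class(motif)
                for i in range(length):
                    rot = motif[i:] + motif[:i]
                    assert canonical_class(rot) == ref
                    assert canonical_class(_revcomp(rot)) == ref


class TestFindSsrs:
    def test_planted_dinucleotide_run(self):
        records, _ = _single_planted("AG", 10)
        (locus,) = find_ssrs(records, min_scaffold_len=1000)
        assert (locus.period, locus.repeat_count, locus.motif) == (2, 10, "AG")
        assert locus.end - locus.start + 1 == 20
        assert locus.canonical_class == "AG/CT"

    def test_mononucleotide_threshold_boundary(self):
        below, _ = _single_planted("A", 9)
        at, _ = _single_planted("A", 10)
        assert find_ssrs(below, min_scaffold_len=1000) == []
        (locus,) = find_ssrs(at, min_scaffold_len=1000)
        assert (locus.period, locus.repeat_count) == (1, 10)

    def test_short_scaffolds_skipped_entirely(self):
        records, _ = _single_planted("AG", 10)
        assert find_ssrs(records, min_scaffold_len=2000) == []

    def test_runs_broken_at_n(self):
        clean, _ = simulate_scaffolds(
            GenomeSimSpec(n_scaffolds=1, length_range=(1300, 1300), seed=55)
        )
        base = clean[0].residues
        # C guards stop the background from extending the A-runs
        split = base[:499] + "C" + "A" * 6 + "N" + "A" * 6 + "C" + base[514:]
        joined = base[:499] + "C" + "A" * 12 + "C" + base[514:]
        rec_split = SequenceRecord(id="s", residues=split)
        rec_joined = SequenceRecord(id="s", residues=joined)
        assert find_ssrs([rec_split], min_scaffold_len=1000) == []
        (locus,) = find_ssrs([rec_joined], min_scaffold_len=1000)
        assert (locus.motif, locus.repeat_count) == ("A", 12)

    def test_partial_trailing_unit_not_counted(self):
        records, _ = _single_planted("AG", 6)
        (locus,) = find_ssrs(records, min_scaffold_len=1000)
        # planted (AG)x6; any trailing partial unit must not raise the count
        assert locus.repeat_count == 6
        assert locus.end - locus.start + 1 == 12

    def test_recovers_planted_truth_exactly(self, planted_scaffolds):
        records, truth = planted_scaffolds
        mined = find_ssrs(records, min_scaffold_len=1000)
        assert {l.key() for l in mined} == {l.key() for l in truth}

    def test_strand_consistency(self, planted_scaffolds):
        records, _ = planted_scaffolds
        fwd = find_ssrs(records, min_scaffold_len=1000)
        rc_records = [
            SequenceRecord(id=r.id, residues=_revcomp(r.residues)) for r in records
        ]
        rev = find_ssrs(rc_records, min_scaffold_len=1000)
        assert sorted(l.canonical_class for l in fwd) == sorted(
            l.canonical_class for l in rev
        )
        lengths = {r.id: len(r) for r in records}
        fwd_coords = {(l.scaffold_id, l.start, l.end) for l in fwd}
        mirrored = {
            (l.scaffold_id, lengths[l.scaffold_id] - l.end + 1,
             lengths[l.scaffold_id] - l.start + 1)
            for l in rev
        }
        assert fwd_coords == mirrored

    def test_no_overlapping_loci_reported(self, planted_scaffolds):
        records, _ = planted_scaffolds
        by_scaffold = {}
        for l in find_ssrs(records, min_scaffold_len=1000):
            by_scaffold.setdefault(l.scaffold_id, []).append((l.start, l.end))
        for spans in by_scaffold.values():
            spans.sort()
            assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_matches_regex_oracle_on_random_scaffolds(self):
        spec = GenomeSimSpec(
            n_scaffolds=10, length_range=(3000, 6000), gc_target=0.38, seed=77
        )
        records, _ = simulate_scaffolds(spec)
        # re-randomize away from the generator's cleanliness guarantee by
        # mining with lower thresholds than the generator screens against
        thresholds = {1: 8, 2: 5, 3: 4, 4: 4, 5: 4, 6: 4}
        mined = {l.key() for l in find_ssrs(records, thresholds, min_scaffold_len=1000)}
        assert mined == regex_ssr_oracle(records, thresholds, 1000)


class TestSummaries:
    def test_mean_distance_from_published_scale(self):
        assert mean_distance_kb(86.51e6, 27153) == 3.19

    def test_zero_loci(self):
        dist, mean_kb = summarize_ssrs([], total_scanned_length=1000.0)
        assert dist.grand_total == 0 and mean_kb is None

    def test_distribution_equals_truth_tally(self, planted_scaffolds):
        records, truth = planted_scaffolds
        mined = find_ssrs(records, min_scaffold_len=1000)
        dist, _ = summarize_ssrs(mined, sum(len(r) for r in records))
        truth_dist = MotifDistribution.from_loci(truth)
        assert dist.cells == truth_dist.cells
        assert dist.grand_total == len(truth)
        assert sum(dist.period_totals.values()) == dist.grand_total

    def test_share_pct_rounding(self):
        assert share_pct(1, 3) == 33.33
        with pytest.raises(ValueError):
            share_pct(1, 0)
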