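import numpy as np
import pytest

from ssrsurvey.io_formats import SequenceRecord
from ssrsurvey.kmer_profile import (
    KmerHistogram,
    SpectrumUninformativeError,
    count_kmers,
    estimate_genome_size,
    estimate_heterozygosity,
    estimate_peak_depth,
    estimate_repeat_fraction,
    find_error_cutoff,
    kmer_fraction_to_het_rate,
    profile_genome,
)
from ssrsurvey.synthetic_data import SpectrumSimSpec, simulate_kmer_histogram


def _gaussian_bump(center, height, width=6):
    return {
        center + d: max(1, int(height * np.exp(-(d * d) / (2 * (width / 3) ** 2))))
        for d in range(-width, width + 1)
    }


class TestCountKmers:
    def test_distinct_singletons(self):
        h = count_kmers([SequenceRecord(id="s", residues="ACGT")], k=2)
        assert h.counts == {1: 3}

    def test_repeated_kmer_multiplicity(self):
        h = count_kmers([SequenceRecord(id="s", residues="AAAA")], k=2)
        assert h.counts == {3: 1}

    def test_canonical_merges_reverse_complements(self):
        # windows of ACGT at k=2: AC, CG, GT; canon(GT) = AC
        h = count_kmers([SequenceRecord(id="s", residues="ACGT")], k=2, canonical=True)
        assert h.counts == {1: 1, 2: 1}

    def test_windows_with_n_skipped(self):
        h = count_kmers([SequenceRecord(id="s", residues="ACNGT")], k=2)
        assert h.counts == {1: 2}  # AC and GT only

    def test_total_observations_equal_window_count_oracle(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGTN"), size=100_000, p=[0.24] * 4 + [0.04]))
        k = 17
        h = count_kmers([SequenceRecord(id="s", residues=seq)], k=k)
        n_windows = sum(
            1
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        )
        assert h.total_observations == n_windows

    def test_k_longer_than_all_records(self):
        with pytest.raises(ValueError, match="no k-mers"):
            count_kmers([SequenceRecord(id="s", residues="ACG")], k=5)


class TestErrorCutoff:
    def test_first_valley_on_sparse_support(self):
        h = KmerHistogram(k=17, counts={1: 1000, 2: 100, 3: 5, 10: 50, 11: 80, 12: 50})
        assert find_error_cutoff(h) == 3

    def test_rising_spectrum_has_no_error_mass(self):
        h = KmerHistogram(k=17, counts={1: 5, 2: 50, 3: 80, 4: 40})
        assert find_error_cutoff(h) == 1

    def test_peak_at_support_start_above_one(self):
        h = KmerHistogram(k=17, counts={40: 900, 41: 700, 42: 100})
        assert find_error_cutoff(h) == 40

    def test_pure_error_spectrum_rejected(self):
        h = KmerHistogram(k=17, counts={1: 1000, 2: 100, 3: 5})
        with pytest.raises(SpectrumUninformativeError):
            find_error_cutoff(h)

    def test_simulated_error_component_cut_below_quarter_coverage(self):
        spec = SpectrumSimSpec(
            genome_size=1_000_000, coverage=44, error_kmer_mass=0.2, seed=2
        )
        cutoff = find_error_cutoff(simulate_kmer_histogram(spec))
        assert 1 < cutoff < 44 / 4


class TestPeakDepth:
    def test_single_peak(self):
        h = KmerHistogram(k=17, counts=_gaussian_bump(30, 1000))
        assert estimate_peak_depth(h, error_cutoff=1) == 30

    def test_taller_half_depth_peak_yields_homozygous_depth(self):
        counts = _gaussian_bump(22, 1000)
        for d, v in _gaussian_bump(44, 800).items():
            counts[d] = counts.get(d, 0) + v
        h = KmerHistogram(k=17, counts=counts)
        assert estimate_peak_depth(h, error_cutoff=1) == 44

    def test_override_wins(self):
        h = KmerHistogram(k=17, counts=_gaussian_bump(30, 1000))
        assert estimate_peak_depth(h, error_cutoff=1, override=22) == 22

    def test_no_maximum_raises(self):
        h = KmerHistogram(k=17, counts={5: 10})
        with pytest.raises(SpectrumUninformativeError):
            estimate_peak_depth(h, error_cutoff=6)

    def test_recovery_on_heterozygous_spectrum(self):
        spec = SpectrumSimSpec(
            genome_size=5_000_000, coverage=44, het_rate=0.017, seed=3
        )
        h = simulate_kmer_histogram(spec)
        peak = estimate_peak_depth(h, find_error_cutoff(h))
        assert abs(peak - 44) <= 1


class TestGenomeSize:
    def test_algebraic_identity(self):
        h = KmerHistogram(k=17, counts={3: 7, 44: 900, 100: 11})
        size, revised = estimate_genome_size(h, peak_depth=44, error_cutoff=10)
        assert size == h.total_observations / 44
        assert revised == (h.total_observations - 3 * 7) / 44

    def test_no_error_mass_means_no_revision(self):
        h = KmerHistogram(k=17, counts={10: 100})
        assert estimate_genome_size(h, 10, 1) == (100.0, 100.0)

    def test_scaling_counts_scales_size_only(self):
        base = simulate_kmer_histogram(
            SpectrumSimSpec(
                genome_size=2_000_000,
                coverage=44,
                het_rate=0.017,
                repeat_fraction=0.3,
                error_kmer_mass=0.05,
                seed=4,
            )
        )
        scaled = KmerHistogram(
            k=base.k, counts={d: 7 * n for d, n in base.counts.items()}
        )
        p1, p2 = profile_genome(base), profile_genome(scaled)
        assert p2.peak_depth == p1.peak_depth
        assert p2.error_cutoff == p1.error_cutoff
        assert p2.genome_size_bp == pytest.approx(7 * p1.genome_size_bp)
        assert p2.het_rate == pytest.approx(p1.het_rate, abs=1e-6)
        assert p2.repeat_fraction == pytest.approx(p1.repeat_fraction, abs=1e-9)


class TestHeterozygosity:
    def test_closed_form_inversion(self):
        # f_het = 0.25 at k = 17 corresponds to r = 1 - 0.75^(1/17)
        assert kmer_fraction_to_het_rate(0.25, 17) == pytest.approx(0.01678, abs=5e-6)

    def test_null_spectrum_estimates_zero(self):
        spec = SpectrumSimSpec(genome_size=5_000_000, coverage=44, seed=6)
        h = simulate_kmer_histogram(spec)
        est = estimate_heterozygosity(h, 44, find_error_cutoff(h))
        assert est is not None and est < 0.001

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_recovery_at_study_rate(self, seed):
        spec = SpectrumSimSpec(
            genome_size=5_000_000, coverage=44, het_rate=0.017, seed=seed
        )
        h = simulate_kmer_histogram(spec)
        cutoff = find_error_cutoff(h)
        peak = estimate_peak_depth(h, cutoff)
        est = estimate_heterozygosity(h, peak, cutoff)
        assert 0.012 <= est <= 0.022


class TestRepeatFraction:
    def test_unimodal_spectrum_has_no_tail(self):
        spec = SpectrumSimSpec(genome_size=2_000_000, coverage=44, seed=8)
        h = simulate_kmer_histogram(spec)
        assert estimate_repeat_fraction(h, 44, find_error_cutoff(h)) < 0.01

    def test_all_mass_far_beyond_peak(self):
        h = KmerHistogram(k=17, counts={440: 1000})
        assert estimate_repeat_fraction(h, 44, 1) == pytest.approx(1.0)

    def test_recovery_at_half_repetitive(self):
        spec = SpectrumSimSpec(
            genome_size=5_000_000, coverage=44, repeat_fraction=0.5, seed=9
        )
        h = simulate_kmer_histogram(spec)
        cutoff = find_error_cutoff(h)
        peak = estimate_peak_depth(h, cutoff)
        assert 0.4 <= estimate_repeat_fraction(h, peak, cutoff) <= 0.6
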