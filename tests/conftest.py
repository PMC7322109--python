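import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ssrsurvey.synthetic_data import GenomeSimSpec, PopSimSpec, simulate_genotypes, simulate_scaffolds

#: motif/count pool used to plant qualifying SSRs of every period
PLANT_POOL = [
    ("A", 12),
    ("T", 10),
    ("AG", 10),
    ("AT", 8),
    ("AC", 6),
    ("AAT", 8),
    ("AAG", 5),
    ("ATC", 6),
    ("AAAT", 5),
    ("ACAT", 6),
    ("AAAAT", 5),
    ("AATCG", 5),
    ("AAAAAT", 5),
    ("AATCGG", 5),
]


def planted_spec(n_scaffolds, n_planted, seed, length=5000):
    """A scaffold spec with ``n_planted`` qualifying SSRs spread round-robin."""
    planted = []
    used = {}
    for i in range(n_planted):
        motif, count = PLANT_POOL[i % len(PLANT_POOL)]
        sc = i % n_scaffolds
        slot = used.get(sc, 0)
        start = 300 + slot * 1200  # keeps loci disjoint and >= 50 bp from ends
        used[sc] = slot + 1
        planted.append((motif, count, sc, start))
    return GenomeSimSpec(
        n_scaffolds=n_scaffolds,
        length_range=(length, length),
        gc_target=0.38,
        planted_ssrs=tuple(planted),
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_scaffolds():
    """20 scaffolds of 5 kb carrying 30 planted SSRs, with the truth table."""
    return simulate_scaffolds(planted_spec(n_scaffolds=20, n_planted=30, seed=11))


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two-population diploid genotype panel (10 + 5, 36 loci) with truth."""
    spec = PopSimSpec(
        n_pops=2,
        n_per_pop=(10, 5),
        n_loci=36,
        alleles_per_locus=(2, 7),
        divergence=0.5,
        missing_rate=0.05,
        seed=23,
    )
    return simulate_genotypes(spec)
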