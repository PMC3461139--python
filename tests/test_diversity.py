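"""Diversity metrics: gene diversity, rarefaction, F_IS, resampling correction."""

import itertools

import numpy as np
import pytest

from tempomon.datasets import all_haplotype_tables, haplotype_counts
from tempomon.diversity import (
    expected_het_unbiased,
    fis_within,
    haplotype_inventory,
    observed_het,
    rarefied_richness,
    resample_corrected,
    unbiased_gene_diversity,
)
from tempomon.popdata import GenotypeTable, HaplotypeTable

from conftest import hw_table, random_table


@pytest.mark.parametrize(
    "sample_id, expected",
    [("1987", 0.743), ("2000", 0.364), ("Cs-An-02", 0.000)],
)
def test_gene_diversity_published_rows(sample_id, expected):
    """Published per-sample h values reproduce from the frequency rows."""
    counts = haplotype_counts(sample_id)
    assert round(unbiased_gene_diversity(counts), 3) == expected


def test_gene_diversity_requires_two_sequences():
    with pytest.raises(ValueError):
        unbiased_gene_diversity([1])


def test_expected_het_unbiased_cases():
    assert expected_het_unbiased([10]) == 0.0
    # a single heterozygote: 2 copies, He = 2/1 * (1 - 0.5) = 1
    assert expected_het_unbiased([1, 1]) == pytest.approx(1.0)
    # equal-frequency k alleles at large n approaches (k-1)/k
    k = 4
    assert expected_het_unbiased([10_000] * k) == pytest.approx((k - 1) / k, abs=1e-3)


def test_observed_het_direct_count():
    calls = [[(1, 2)]] * 3 + [[(1, 1)]] * 7
    t = GenotypeTable([f"i{j}" for j in range(10)], ["L1"], calls, "s")
    assert observed_het(t, "L1") == pytest.approx(0.3)


def test_rarefied_richness_enumeration_oracle():
    """Expected distinct count at g=2 from explicit subset enumeration."""
    counts = (2, 2)
    pool = [0, 0, 1, 1]
    vals = [len(set(sub)) for sub in itertools.combinations(pool, 2)]
    oracle = np.mean(vals)  # = 5/3
    assert oracle == pytest.approx(5 / 3)
    assert rarefied_richness(counts, 2) == pytest.approx(oracle, abs=1e-12)


def test_rarefied_richness_bounds_and_monotonicity():
    counts = (3, 2, 1)
    assert rarefied_richness(counts, 1) == pytest.approx(1.0)
    assert rarefied_richness(counts, 6) == 3.0  # g = n returns observed exactly
    vals = [rarefied_richness(counts, g) for g in range(1, 7)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        rarefied_richness(counts, 7)


def test_relabeling_invariance(rng):
    counts = [17, 6, 6, 2, 3, 1, 2]
    shuffled = list(counts)
    rng.shuffle(shuffled)
    assert unbiased_gene_diversity(counts) == pytest.approx(
        unbiased_gene_diversity(shuffled)
    )


def test_fis_sign_conventions():
    all_het = GenotypeTable([f"i{j}" for j in range(40)], ["L1"], [[(1, 2)]] * 40, "s")
    _, f = fis_within(all_het)
    assert f < -0.9
    calls = [[(1, 1)]] * 20 + [[(2, 2)]] * 20
    all_hom = GenotypeTable([f"i{j}" for j in range(40)], ["L1"], calls, "s")
    _, f2 = fis_within(all_hom)
    assert f2 == pytest.approx(1.0)


def test_fis_near_zero_under_hw(rng):
    vals = []
    for _ in range(60):
        t = hw_table(rng, 100, 0.4)
        try:
            vals.append(fis_within(t)[1])
        except ValueError:
            pass
    assert abs(np.mean(vals)) < 0.03


def test_unbiasedness_of_expected_het(rng):
    """Mean of the unbiased He over HW samples matches the generating value."""
    p = 0.3
    truth = 1 - (p**2 + (1 - p) ** 2)
    vals = []
    for _ in range(400):
        t = hw_table(rng, 25, p)
        counts = t.allele_counts("L1")
        if len(counts) > 1:
            vals.append(expected_het_unbiased(counts))
        else:
            vals.append(0.0)
    assert np.mean(vals) == pytest.approx(truth, abs=0.01)


def test_resample_corrected_identity_and_determinism(rng):
    t = random_table(rng, n=30, k=5)
    full = resample_corrected(t, n_star=30, B=5, seed=1)
    # subsample == sample: every subsample reproduces the raw statistics
    from tempomon.diversity import sample_diversity

    raw = sample_diversity(t)
    assert full.Hec == pytest.approx(raw.He_mean, abs=1e-12)
    assert full.Hoc == pytest.approx(raw.Ho_mean, abs=1e-12)
    assert full.Nac == pytest.approx(raw.A_mean, abs=1e-12)
    a = resample_corrected(t, n_star=15, B=50, seed=7)
    b = resample_corrected(t, n_star=15, B=50, seed=7)
    assert a.Hec == b.Hec and a.Hoc == b.Hoc and a.Nac == b.Nac and a.ci == b.ci


def test_resample_corrected_matches_hypergeometric_rarefaction(rng):
    """Mean corrected allele number approximates rarefaction at g = 2 n*."""
    t = random_table(rng, n=60, loci=("L1",), k=6)
    corr = resample_corrected(t, n_star=20, B=800, seed=3)
    counts = t.allele_counts("L1")
    oracle = rarefied_richness(counts, 40)
    # subsampling individuals (pairs of copies) vs copies: close but not identical
    assert corr.Nac == pytest.approx(oracle, abs=0.15)


def test_resample_corrected_rejects_small_samples(rng):
    t = random_table(rng, n=6)
    with pytest.raises(ValueError, match="n_star"):
        resample_corrected(t, n_star=15, B=10)


def test_haplotype_inventory_published_and_errors():
    n, per_sample = haplotype_inventory(all_haplotype_tables())
    assert n == 15
    assert per_sample["1999"] == 5
    with pytest.raises(ValueError):
        haplotype_inventory(HaplotypeTable(["a"], [None], "empty"))
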