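"""Weir-Cockerham theta and hierarchical AMOVA."""

import numpy as np
import pytest

from tempomon.amova import amova_three_level, weir_cockerham_fst
from tempomon.popdata import GenotypeTable, HaplotypeTable

from conftest import hw_table, random_table


def wc84_biallelic(tables, locus="L1"):
    """Classic Weir-Cockerham (1984) a, b, c for a biallelic locus.

    Independent transcription of the published moment formulas; serves as
    the oracle for the nested-ANOVA implementation.
    """
    r = len(tables)
    n, p, h = [], [], []
    for t in tables:
        g = t.genotype_matrix(locus)
        g = g[g[:, 0] != 0]
        n.append(len(g))
        p.append((g == 1).sum() / (2 * len(g)))
        h.append((g[:, 0] != g[:, 1]).mean())
    n = np.asarray(n, float)
    p = np.asarray(p)
    h = np.asarray(h)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def test_theta_matches_wc84_oracle(rng):
    tables = [hw_table(rng, n, p, sample_id=f"s{i}") for i, (n, p) in
              enumerate([(30, 0.3), (45, 0.6), (25, 0.8)])]
    per_locus, theta = weir_cockerham_fst(tables)
    a, b, c = wc84_biallelic(tables)
    assert theta == pytest.approx(a / (a + b + c), abs=1e-10)
    assert per_locus["L1"] == pytest.approx(a / (a + b + c), abs=1e-10)


def test_theta_complete_fixation():
    t1 = GenotypeTable([f"a{i}" for i in range(10)], ["L1"], [[(1, 1)]] * 10, "s1")
    t2 = GenotypeTable([f"b{i}" for i in range(10)], ["L1"], [[(2, 2)]] * 10, "s2")
    _, theta = weir_cockerham_fst([t1, t2])
    assert theta == pytest.approx(1.0)


def test_theta_identical_samples_near_zero(rng):
    calls = [[(1 + (i % 2), 1 + ((i // 2) % 2))] for i in range(40)]
    t1 = GenotypeTable([f"a{i}" for i in range(40)], ["L1"], calls, "s1")
    t2 = GenotypeTable([f"b{i}" for i in range(40)], ["L1"], calls, "s2")
    _, theta = weir_cockerham_fst([t1, t2])
    assert abs(theta) < 0.05


def test_theta_monomorphic_error():
    t1 = GenotypeTable(["a"], ["L1"], [[(1, 1)]], "s1")
    t2 = GenotypeTable(["b"], ["L1"], [[(1, 1)]], "s2")
    with pytest.raises(ValueError):
        weir_cockerham_fst([t1, t2])


def amova_ss_oracle(tables, groups):
    """Brute-force sums of squares for the haploid identity-distance AMOVA.

    Computes SSD terms directly from definition (pairwise squared
    distances within cells) and the Excoffier coefficient solution via a
    dense quadratic-form evaluation, independent of the package engine.
    """
    labels, pop, grp = [], [], []
    for p_i, (t, g) in enumerate(zip(tables, groups)):
        for h in t.haplotype:
            labels.append(h)
            pop.append(p_i)
            grp.append(g)
    labels = np.asarray(labels)
    pop = np.asarray(pop)
    grp = np.asarray(grp)
    d2 = (labels[:, None] != labels[None, :]).astype(float)
    N = len(labels)

    def ssd(mask_codes):
        total = 0.0
        for c in np.unique(mask_codes):
            idx = np.where(mask_codes == c)[0]
            total += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
        return total

    full = ssd(np.zeros(N, dtype=int))
    by_grp = ssd(np.unique(grp, return_inverse=True)[1])
    by_pop = ssd(pop)
    return full - by_grp, by_grp - by_pop, by_pop


def test_amova_haploid_components_match_ss_oracle():
    t1 = HaplotypeTable(["a1", "a2", "a3"], ["A", "A", "B"], "s1")
    t2 = HaplotypeTable(["b1", "b2"], ["A", "B"], "s2")
    t3 = HaplotypeTable(["c1", "c2", "c3", "c4"], ["C", "C", "C", "B"], "s3")
    res = amova_three_level(
        [t1, t2, t3], ["g1", "g1", "g2"], mode="haploid_distance", n_perm=0
    )
    ss_ag, ss_ap, ss_wp = amova_ss_oracle([t1, t2, t3], ["g1", "g1", "g2"])
    # reconstruct the expected SS from the package's components through the
    # independent coefficient computation (dense design-matrix traces)
    N = 9
    grp = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1])
    pop = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2])

    def proj(codes):
        P = np.zeros((N, N))
        for c in np.unique(codes):
            idx = np.where(codes == c)[0]
            P[np.ix_(idx, idx)] = 1.0 / idx.size
        return P

    P0 = np.full((N, N), 1.0 / N)
    P1, P2 = proj(grp), proj(pop)
    I = np.eye(N)
    Zs = [proj(grp) * 0, None]  # placeholder
    # coefficient of sigma_m in E[SS_l] = tr((P_l - P_{l-1}) Z_m Z_m')
    Z = {0: (grp[:, None] == grp[None, :]).astype(float),
         1: (pop[:, None] == pop[None, :]).astype(float),
         2: I}
    C = np.zeros((3, 3))
    for li, (Pl, Pl1) in enumerate([(P1, P0), (P2, P1), (I, P2)]):
        for m in range(3):
            C[li, m] = np.trace((Pl - Pl1) @ Z[m])
    sigma = np.linalg.solve(C, np.array([ss_ag, ss_ap, ss_wp]))
    assert res.sigma2_a == pytest.approx(sigma[0], abs=1e-10)
    assert res.sigma2_b == pytest.approx(sigma[1], abs=1e-10)
    assert res.sigma2_w == pytest.approx(sigma[2], abs=1e-10)


def test_amova_null_indices_near_zero(rng):
    tables = [hw_table(rng, 40, 0.5, sample_id=f"s{i}") for i in range(6)]
    res = amova_three_level(tables, ["g1"] * 3 + ["g2"] * 3, n_perm=60, seed=5)
    assert abs(res.F_ST) < 0.05
    assert res.p_ST > 0.01


def test_amova_disjoint_groups_maximal_structure():
    def fixed(allele, sid):
        return GenotypeTable([f"{sid}{i}" for i in range(12)], ["L1"],
                             [[(allele, allele)]] * 12, sid)

    tables = [fixed(1, "a"), fixed(1, "b"), fixed(2, "c"), fixed(2, "d")]
    res = amova_three_level(tables, ["g1", "g1", "g2", "g2"], n_perm=200, seed=9)
    assert res.F_CT == pytest.approx(1.0, abs=1e-9)
    assert res.p_CT <= 2 / (200 + 1) + 0.35  # only 3 distinct group splits exist
    assert res.F_ST == pytest.approx(1.0, abs=1e-9)
    assert res.p_ST <= 2 / 201


def test_amova_group_validation(rng):
    tables = [random_table(rng, 10, sample_id=f"s{i}") for i in range(2)]
    with pytest.raises(ValueError, match="2 groups"):
        amova_three_level(tables, ["g1", "g1"], n_perm=0)


def test_amova_permutation_pvalues_uniform_under_null(rng):
    """Permutation p for F_ST is uniform when all samples are panmictic."""
    ps = []
    for _ in range(60):
        tables = [hw_table(rng, 12, 0.5, sample_id=f"s{i}") for i in range(4)]
        res = amova_three_level(tables, ["g1", "g1", "g2", "g2"], n_perm=39, seed=rng)
        ps.append(res.p_ST)
    assert 0.35 < np.mean(ps) < 0.65
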