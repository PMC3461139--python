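"""Temporal and single-sample effective-size estimators."""

import numpy as np
import pytest

from tempomon.effective_size import (
    INF,
    TemporalPairStats,
    _expected_r2,
    _invert_r2,
    broodstock_ne,
    haploid_moments_nef,
    ld_ne,
    mlne_ne,
    moments_ne,
    overlap_correction,
    temporal_fc,
    temporal_fs,
    temporal_pair,
    tempofs_ne,
)
from tempomon.simulate import SimConfig, simulate


def pair_from(x, y, S0=50, St=50, t=1, plan="II", N=None, ploidy=2, with_counts=False):
    xs = {f"L{i}": np.asarray(v, dtype=float) for i, v in enumerate(x)}
    ys = {f"L{i}": np.asarray(v, dtype=float) for i, v in enumerate(y)}
    cx = cy = None
    if with_counts:
        cx = {k: v * ploidy * S0 for k, v in xs.items()}
        cy = {k: v * ploidy * St for k, v in ys.items()}
    return TemporalPairStats(
        x=xs, y=ys, S0=S0, St=St, t=t, plan=plan, N=N, ploidy=ploidy,
        counts_x=cx or {}, counts_y=cy or {},
    )


def test_fc_hand_example_exact():
    pair = pair_from([[0.5, 0.5]], [[0.6, 0.4]])
    fc, df = temporal_fc(pair)
    # both alleles contribute 0.01/0.25
    assert fc == pytest.approx(0.04, abs=1e-12)
    assert df == 1


def test_fs_hand_example_exact():
    pair = pair_from([[0.5, 0.5]], [[0.6, 0.4]])
    # sum (x-y)^2 = 0.02; sum z(1-z) = 0.495
    assert temporal_fs(pair) == pytest.approx(0.02 / 0.495, abs=1e-12)


def test_fc_zero_when_frequencies_identical():
    pair = pair_from([[0.3, 0.7]], [[0.3, 0.7]])
    assert temporal_fc(pair)[0] == 0.0


def test_fc_relabeling_and_swap_invariance():
    pair = pair_from([[0.2, 0.3, 0.5]], [[0.25, 0.35, 0.4]])
    relabeled = pair_from([[0.5, 0.3, 0.2]], [[0.4, 0.35, 0.25]])
    swapped = pair_from([[0.25, 0.35, 0.4]], [[0.2, 0.3, 0.5]])
    assert temporal_fc(pair)[0] == pytest.approx(temporal_fc(relabeled)[0], abs=1e-12)
    assert temporal_fc(pair)[0] == pytest.approx(temporal_fc(swapped)[0], abs=1e-12)


def test_moments_hand_example():
    pair = pair_from([[0.5, 0.5]], [[0.6, 0.4]], S0=50, St=50, t=1, plan="II")
    est = moments_ne(pair)
    # F' = 0.04 - 1/100 - 1/100 = 0.02 -> Ne = 1/(2*0.02) = 25
    assert est.point == pytest.approx(25.0, abs=1e-9)


def test_plan_convergence():
    """Plan I converges to Plan II as the census grows."""
    p2 = moments_ne(pair_from([[0.5, 0.5]], [[0.6, 0.4]], plan="II"))
    for N, tol in [(1e6, 1e-4), (1e9, 1e-7)]:
        p1 = moments_ne(pair_from([[0.5, 0.5]], [[0.6, 0.4]], plan="I", N=N))
        assert abs(p1.point - p2.point) / p2.point < tol


def test_infinity_semantics_identical_samples():
    pair = pair_from(
        [[0.5, 0.5], [0.25, 0.75]], [[0.5, 0.5], [0.25, 0.75]],
        S0=100, St=100, with_counts=True,
    )
    assert moments_ne(pair).point == INF
    assert tempofs_ne(pair).point == INF
    assert mlne_ne(pair).point == INF  # MLE at the top grid bound


def test_ld_infinity_when_r2_at_expectation():
    assert _invert_r2(0.0, 100)[0] == INF
    assert _invert_r2(-1e-4, 100)[0] == INF


def test_ld_inversion_hand_example():
    # r2_mean = 0.03 at S = 100: E = 0.010319, r2' = 0.019681, Ne = 14.52
    r2p = 0.03 - _expected_r2(100.0)
    assert r2p == pytest.approx(0.019681, abs=1e-9)
    ne, below = _invert_r2(r2p, 100.0)
    assert not below
    assert ne == pytest.approx(14.52, abs=5e-3)


def test_haploid_moments_hand_example():
    pair = pair_from([[0.5, 0.5]], [[0.6, 0.4]], S0=100, St=100, ploidy=1)
    est = haploid_moments_nef(pair)
    # F' = 0.04 - 1/100 - 1/100 = 0.02 -> Nef = 1/0.02 = 50
    assert est.point == pytest.approx(50.0, abs=1e-9)
    same = pair_from([[0.5, 0.5]], [[0.5, 0.5]], S0=100, St=100, ploidy=1)
    assert haploid_moments_nef(same).point == INF


def test_overlap_correction_scaling():
    est = moments_ne(pair_from([[0.5, 0.5]], [[0.6, 0.4]]))
    assert overlap_correction(est, C=1.27, G=1.27).point == pytest.approx(est.point)
    doubled = overlap_correction(est, C=2.54, G=1.27)
    assert doubled.point == pytest.approx(2 * est.point)
    assert doubled.corrected_for_overlap
    inf_est = moments_ne(pair_from([[0.5, 0.5]], [[0.5, 0.5]]))
    assert overlap_correction(inf_est, C=2.54, G=1.27).point == INF
    with pytest.raises(ValueError):
        overlap_correction(est, C=0.0, G=1.27)


def test_broodstock_formula():
    assert broodstock_ne(10, 10) == 20.0
    assert broodstock_ne(1, 3) == pytest.approx(3.0)
    assert broodstock_ne(1, 1) == 2.0
    with pytest.raises(ValueError):
        broodstock_ne(0, 5)


def test_mlne_toy_within_factor_two_of_moments():
    pair = pair_from([[0.5, 0.5]], [[0.6, 0.4]], S0=50, St=50, t=1, with_counts=True)
    est = mlne_ne(pair)
    assert np.isfinite(est.point)
    assert 25.0 / 2 <= est.point <= 25.0 * 2


def test_mlne_requires_counts():
    pair = pair_from([[0.5, 0.5]], [[0.6, 0.4]])
    with pytest.raises(ValueError, match="counts"):
        mlne_ne(pair)


def test_tempofs_single_locus_flagged():
    pair = pair_from([[0.5, 0.5]], [[0.6, 0.4]])
    est = tempofs_ne(pair)
    assert np.isfinite(est.point)
    assert np.isnan(est.ci_low) and np.isnan(est.ci_high)


def test_temporal_pair_requires_t():
    with pytest.raises(ValueError):
        pair_from([[0.5, 0.5]], [[0.6, 0.4]], t=0)


def test_ld_ne_on_simulated_sample_is_positive():
    cfg = SimConfig(n_generations=4, Nc=500, true_Ne=100.0, L=9, k_alleles=8,
                    init_alpha=5.0, sampling={4: 60}, seed=12)
    samples, _ = simulate(cfg)
    est, stats = ld_ne(samples[0].genotypes, Pcrit=0.02)
    assert stats.r2_mean > 0
    assert stats.n_comparisons > 0
    assert est.point > 0 or est.point == INF


def test_estimator_swap_invariance_on_tables():
    cfg = SimConfig(n_generations=2, Nc=400, true_Ne=80.0, L=4, k_alleles=4,
                    init_alpha=5.0, sampling={0: 40, 2: 40}, seed=3)
    samples, _ = simulate(cfg)
    a, b = samples
    fwd = temporal_pair(a.genotypes, b.genotypes, t=2)
    rev = temporal_pair(b.genotypes, a.genotypes, t=2)
    assert temporal_fc(fwd)[0] == pytest.approx(temporal_fc(rev)[0], abs=1e-12)
    assert temporal_fs(fwd) == pytest.approx(temporal_fs(rev), abs=1e-12)
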