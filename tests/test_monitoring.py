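"""Demography/environment/supplementation association tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tempomon.monitoring import (
    align_series,
    broodstock_regression,
    correlation_tests,
    kruskal_wallis_by_reach,
    pre_post_comparison,
    runoff_score,
    transform_cpue,
)


def test_transform_cpue():
    out = transform_cpue([0.0, 99.0, 9.0])
    assert out[0] == 0.0
    assert out[1] == pytest.approx(2.0)
    assert out[2] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        transform_cpue([-1.0])


@pytest.mark.parametrize("days_above, expected", [(10, 10), (20, 15), (35, 20),
                                                  (14, 10), (30, 15), (31, 20)])
def test_runoff_scoring_rule(days_above, expected):
    flows = np.full(61, 1000.0)
    flows[:days_above] = 5000.0
    assert runoff_score(flows) == expected


def test_runoff_requires_complete_window():
    with pytest.raises(ValueError):
        runoff_score(np.full(60, 1000.0))
    with pytest.raises(ValueError):
        runoff_score(np.r_[np.full(60, 1000.0), np.nan])


def test_align_series_lags():
    # env of 1999 pairs with the temporal estimate labeled 2000 (its
    # sample-pair start year): conditions affect the next generation
    ne = {2000: 115.0, 2001: 150.0}
    env = {1999: 1.2, 2000: 2.5, 2001: 0.7}
    paired = align_series(ne, env, lag=1).set_index("year")
    assert paired.loc[1999, "metric"] == 115.0
    assert paired.loc[2000, "metric"] == 150.0
    # lag 0 is the identity pairing
    ident = align_series(env, env, lag=0)
    assert (ident["metric"] == ident["env"]).all()
    with pytest.raises(ValueError):
        align_series({1990: 1.0}, {2005: 1.0}, lag=1)


def test_ld_lag_two_matches_design():
    """The LD estimate from a year-2000 sample pairs with 1998 conditions."""
    ld = {2000: 900.0}
    env = {1998: 3.1, 1999: 2.0}
    paired = align_series(ld, env, lag=2)
    assert len(paired) == 1
    assert paired.iloc[0]["year"] == 1998
    assert paired.iloc[0]["env"] == 3.1
    assert paired.iloc[0]["metric"] == 900.0


def test_spearman_hand_ranked_oracle():
    x = [3.0, 1.0, 4.0, 1.5, 5.0]
    y = [2.0, 0.5, 3.5, 1.0, 2.5]
    df = pd.DataFrame({"year": range(5), "metric": x, "env": y})
    res = correlation_tests(df, method="spearman")
    # brute-force rank correlation
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert res.statistic == pytest.approx(oracle, abs=1e-12)


def test_correlation_monotone_limits():
    df = pd.DataFrame({"year": range(5), "metric": [1, 2, 3, 4, 5],
                       "env": [10, 20, 30, 40, 50]})
    assert correlation_tests(df).statistic == pytest.approx(1.0)
    df["env"] = df["env"][::-1].to_numpy()
    assert correlation_tests(df).statistic == pytest.approx(-1.0)


def test_infinite_ne_excluded_with_count():
    df = pd.DataFrame({"year": range(5), "metric": [1, 2, np.inf, 4, 5],
                       "env": [1, 2, 3, 4, 5]})
    res = correlation_tests(df)
    assert res.n_used == 4
    assert res.n_excluded_infinite == 1


def test_mannwhitney_exact_matches_enumeration():
    """Exact p on a 3-vs-3 toy equals full enumeration of rank splits."""
    before = [1.0, 2.0, 3.0]
    after = [4.0, 5.0, 2.5]
    series = {2001: 1.0, 2002: 2.0, 2003: 3.0, 2004: 4.0, 2005: 5.0, 2006: 2.5}
    res = pre_post_comparison(series, split_year=2004)

    pooled = before + after
    obs_u = sum(1 for b in before for a in after if b < a) + \
        0.5 * sum(1 for b in before for a in after if b == a)
    obs_dev = abs(obs_u - 4.5)
    count = 0
    total = 0
    for combo in itertools.combinations(range(6), 3):
        grp1 = [pooled[i] for i in combo]
        grp2 = [pooled[i] for i in range(6) if i not in combo]
        u = sum(1 for b in grp1 for a in grp2 if b < a) + \
            0.5 * sum(1 for b in grp1 for a in grp2 if b == a)
        total += 1
        if abs(u - 4.5) >= obs_dev - 1e-12:
            count += 1
    assert res.p_value == pytest.approx(count / total, abs=1e-12)


def test_pre_post_requires_both_eras():
    with pytest.raises(ValueError):
        pre_post_comparison({2001: 1.0, 2004: 2.0, 2005: 3.0})


def test_broodstock_regression_noise_free_slope():
    bs = {f"lot{i}": float(20 + 10 * i) for i in range(6)}
    ned = {k: 0.5 * v for k, v in bs.items()}
    res = broodstock_regression(bs, ned)
    assert res.extra["slope"] == pytest.approx(0.5)
    assert res.statistic == pytest.approx(1.0)
    assert res.extra["df"] == 4


def test_broodstock_regression_excludes_infinite():
    bs = {"a": 20.0, "b": 30.0, "c": 40.0, "d": 50.0}
    ned = {"a": 10.0, "b": 16.0, "c": np.inf, "d": 24.0}
    res = broodstock_regression(bs, ned)
    assert res.n_used == 3
    assert res.n_excluded_infinite == 1
    with pytest.raises(ValueError):
        broodstock_regression({"a": 20.0, "b": 20.0, "c": 20.0},
                              {"a": 1.0, "b": 2.0, "c": 3.0})


def test_kruskal_matches_brute_force_ranks():
    groups = {"Angostura": [0.80, 0.82, 0.81], "Isleta": [0.79, 0.83],
              "SanAcacia": [0.85, 0.86, 0.84]}
    res = kruskal_wallis_by_reach(groups)
    h, p = stats.kruskal(*groups.values())
    assert res.statistic == pytest.approx(h, abs=1e-12)
    assert res.p_value == pytest.approx(p, abs=1e-12)
    ident = {"a": [1.0, 1.0], "b": [1.0, 1.0]}
    with pytest.raises(ValueError):
        # all-tied groups have an undefined H in scipy; degenerate input
        kruskal_wallis_by_reach({"a": [1.0], "b": [1.0, 2.0]})


def test_year_order_invariance():
    series = {y: float(v) for y, v in zip(range(2000, 2008), [1, 5, 2, 4, 3, 6, 7, 8])}
    shuffled = dict(reversed(list(series.items())))
    a = pre_post_comparison(series, split_year=2004)
    b = pre_post_comparison(shuffled, split_year=2004)
    assert a.statistic == b.statistic and a.p_value == b.p_value
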