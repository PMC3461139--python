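"""Association tests linking demography, environment, and supplementation
to the genetic monitoring series.

Covers the CPUE log transform, the categorical spring-runoff score, the
generation-lag pairing of environmental and genetic series (temporal Ne
estimates lag the environment by one year, LD estimates by two), and the
prediction tests: rank correlations, before/after-supplementation
Mann-Whitney comparisons, the broodstock-size regression, and the
by-river-reach Kruskal-Wallis comparison. Infinite Ne values never enter a
rank or regression silently; exclusion counts are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "transform_cpue",
    "runoff_score",
    "align_series",
    "correlation_tests",
    "pre_post_comparison",
    "broodstock_regression",
    "kruskal_wallis_by_reach",
]


def transform_cpue(cpue, base: str = "log10", offset: float = 1.0) -> np.ndarray:
    """Log-transform a catch-per-unit-effort vector: log10(x + 1) by default."""
    arr = np.asarray(cpue, dtype=float)
    if (arr < 0).any():
        raise ValueError("CPUE values must be nonnegative")
    if base == "log10":
        return np.log10(arr + offset)
    if base == "ln":
        return np.log(arr + offset)
    raise ValueError("base must be 'log10' or 'ln'")


def runoff_score(daily_discharge, threshold: float = 3000.0) -> int:
    """Categorical spring-runoff score from daily May 1 - June 30 discharge.

    With d = number of days above the threshold (cfs): 10 if d <= 14,
    15 if 14 < d <= 30, 20 if d > 30. The printed rule leaves d = 30
    uncovered between its middle and top categories; it is assigned to 15
    (the middle band is read as inclusive of its upper edge).
    """
    arr = np.asarray(daily_discharge, dtype=float)
    if arr.size != 61:
        raise ValueError("expected 61 daily values (May 1 - June 30)")
    if np.isnan(arr).any():
        raise ValueError("missing days in discharge record")
    d = int((arr > threshold).sum())
    if d > 30:
        return 20
    if d > 14:
        return 15
    return 10


def align_series(
    metric: dict[int, float] | pd.Series,
    env: dict[int, float] | pd.Series,
    lag: int = 1,
) -> pd.DataFrame:
    """Pair a year-indexed genetic metric with an environmental series.

    Environmental conditions of year t are matched with the metric labeled
    year t + lag: conditions affect the generation sampled ``lag`` years
    later (lag 1 for temporal Ne labeled by its first sample year, lag 2
    for LD Ne, which reflects the parents of the sampled cohort; lag 0 is
    the identity pairing). Years lacking either value are dropped; the
    returned frame has columns (year, metric, env) with ``year`` the
    environmental year.
    """
    m = pd.Series(metric, dtype=float)
    e = pd.Series(env, dtype=float)
    rows = []
    for year, env_val in e.items():
        key = year + lag
        if key in m.index:
            rows.append((year, m[key], env_val))
    # keep infinities (excluded downstream with a report); drop only NaN
    df = pd.DataFrame(rows, columns=["year", "metric", "env"]).dropna()
    if df.empty:
        raise ValueError("no overlapping years after lagging")
    return df


@dataclass
class AssociationResult:
    statistic: float
    p_value: float | None
    n_used: int
    n_excluded_infinite: int
    method: str
    extra: dict | None = None


def correlation_tests(paired: pd.DataFrame, method: str = "spearman") -> AssociationResult:
    """Spearman rank correlation or OLS regression on a paired table.

    Infinite metric values (Ne at the sampling floor) are excluded and the
    exclusion count reported; fewer than 4 finite pairs is flagged as
    underpowered (statistic returned, p None).
    """
    x = paired["metric"].to_numpy(dtype=float)
    y = paired["env"].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    n_excl = int((~finite).sum())
    x, y = x[finite], y[finite]
    n = x.size
    if method == "spearman":
        if n < 2:
            raise ValueError("need at least 2 finite pairs")
        rho, p = stats.spearmanr(x, y)
        return AssociationResult(float(rho), float(p) if n >= 4 else None, n, n_excl, "spearman")
    if method == "ols":
        if n < 3 or np.unique(x).size < 2:
            raise ValueError("degenerate design for OLS")
        res = stats.linregress(x, y)
        extra = {"slope": res.slope, "intercept": res.intercept, "r2": res.rvalue**2}
        return AssociationResult(float(res.rvalue**2), float(res.pvalue) if n >= 4 else None,
                                 n, n_excl, "ols", extra)
    raise ValueError("method must be 'spearman' or 'ols'")


def pre_post_comparison(
    by_year: dict[int, float] | pd.Series,
    split_year: int = 2004,
) -> AssociationResult:
    """Mann-Whitney U comparison of a yearly metric before/after a split.

    Years < split_year form the "before" era, years >= split_year the
    "after" era (the split year is the first year of the after group).
    Uses the exact null distribution when sample sizes permit.
    """
    s = pd.Series(by_year, dtype=float).dropna()
    before = s[s.index < split_year].to_numpy()
    after = s[s.index >= split_year].to_numpy()
    if before.size < 2 or after.size < 2:
        raise ValueError("each era needs at least 2 years")
    method = "exact" if (before.size <= 8 and after.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(before, after, alternative="two-sided", method=method)
    return AssociationResult(float(res.statistic), float(res.pvalue),
                             int(before.size + after.size), 0, f"mannwhitney_{method}")


def broodstock_regression(
    broodstock_ne: dict[str, float],
    ne_d: dict[str, float],
) -> AssociationResult:
    """OLS of LD-based Ne on broodstock effective size across hatchery lots.

    Lots with infinite LD estimates are excluded (count reported);
    at least 3 finite lots and a non-degenerate design are required.
    """
    lots = sorted(set(broodstock_ne) & set(ne_d))
    x = np.array([broodstock_ne[l] for l in lots], dtype=float)
    y = np.array([ne_d[l] for l in lots], dtype=float)
    finite = np.isfinite(y) & np.isfinite(x)
    n_excl = int((~finite).sum())
    x, y = x[finite], y[finite]
    if x.size < 3:
        raise ValueError("need at least 3 lots with finite LD-Ne")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: single broodstock-Ne value")
    res = stats.linregress(x, y)
    return AssociationResult(
        statistic=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_used=int(x.size),
        n_excluded_infinite=n_excl,
        method="ols",
        extra={"slope": float(res.slope), "intercept": float(res.intercept),
               "df": int(x.size - 2)},
    )


def kruskal_wallis_by_reach(groups: dict[str, list[float]]) -> AssociationResult:
    """Kruskal-Wallis one-way ANOVA on ranks across river reaches.

    ``groups`` maps reach name to the yearly values of one corrected
    diversity metric; ties are handled by midranks with the standard
    correction.
    """
    arrays = []
    for reach, values in groups.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise ValueError(f"reach {reach!r} has fewer than 2 values")
        arrays.append(arr)
    if len(arrays) < 2:
        raise ValueError("need at least 2 reaches")
    h, p = stats.kruskal(*arrays)
    return AssociationResult(float(h), float(p), int(sum(a.size for a in arrays)), 0, "kruskal")
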