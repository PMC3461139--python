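"""Effective population size estimators for temporal and single-sample data.

Implements the estimators used in temporal genetic monitoring:

* the moments temporal method on the Nei-Tajima standardized variance Fc,
  with the sampling-variance correction for Plan I (sampling before
  reproduction, with replacement, census size N enters) or Plan II designs
  and a chi-square confidence interval on Fc;
* the Jorde-Ryman unbiased drift statistic Fs with its small-sample bias
  correction and a delete-one-locus jackknife CI;
* a pseudo-maximum-likelihood temporal estimator: each allele (vs rest) is
  a binomial observation of a latent frequency evolving by Wright-Fisher
  transitions on a discretized frequency grid, and the pseudo-likelihood
  (product over alleles and loci) is maximized over a grid of Ne values;
* the single-sample linkage-disequilibrium method on the Burrows composite
  disequilibrium, with the standard sampling-expectation adjustment and
  random-mating inversion;
* a haploid (mtDNA) variant of the moments method estimating the female
  effective size, and the multiplicative correction of consecutive-year
  estimates for overlapping generations;
* the sex-ratio broodstock effective size 4*Nm*Nf / (Nm + Nf).

All estimators share the infinity convention: when the drift (or
disequilibrium) signal net of sampling is <= 0 the point estimate is
+infinity, never negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import stats

from .popdata import GenotypeTable

__all__ = [
    "TemporalPairStats",
    "NeEstimate",
    "LDStats",
    "temporal_pair",
    "temporal_fc",
    "temporal_fs",
    "moments_ne",
    "tempofs_ne",
    "mlne_ne",
    "ld_ne",
    "haploid_moments_nef",
    "overlap_correction",
    "broodstock_ne",
]

INF = float("inf")


@dataclass
class TemporalPairStats:
    """Allele frequencies of two temporal samples of one population.

    ``x`` and ``y`` map locus -> frequency vector at the first and second
    sample; ``counts_x``/``counts_y`` hold the corresponding observed copy
    counts (used by the likelihood method). ``S0``/``St`` are sample sizes
    in individuals; gene copies are ``ploidy * S``. ``t`` is the number of
    generations elapsed; ``N`` the census size entering the Plan I
    correction.
    """

    x: dict[str, np.ndarray]
    y: dict[str, np.ndarray]
    S0: float
    St: float
    t: int
    plan: str = "II"
    N: float | None = None
    ploidy: int = 2
    counts_x: dict[str, np.ndarray] = field(default_factory=dict)
    counts_y: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1 generation")
        if self.plan not in {"I", "II"}:
            raise ValueError("plan must be 'I' or 'II'")
        if self.plan == "I" and self.N is None:
            raise ValueError("Plan I requires a census size N")
        for locus in self.x:
            fx = np.asarray(self.x[locus], dtype=float)
            fy = np.asarray(self.y[locus], dtype=float)
            if fx.shape != fy.shape:
                raise ValueError(f"locus {locus}: x and y lengths differ")
            for f in (fx, fy):
                if f.size and not np.isclose(f.sum(), 1.0, atol=1e-6):
                    raise ValueError(f"locus {locus}: frequencies do not sum to 1")
            self.x[locus] = fx
            self.y[locus] = fy

    @property
    def harmonic_S(self) -> float:
        return 2.0 / (1.0 / self.S0 + 1.0 / self.St)


def temporal_pair(
    first: GenotypeTable,
    second: GenotypeTable,
    t: int,
    plan: str = "II",
    N: float | None = None,
) -> TemporalPairStats:
    """Build :class:`TemporalPairStats` from two genotype tables.

    Only loci present in both tables are used; the allele set per locus is
    the union over both samples.
    """
    x: dict[str, np.ndarray] = {}
    y: dict[str, np.ndarray] = {}
    cx: dict[str, np.ndarray] = {}
    cy: dict[str, np.ndarray] = {}
    for locus in first.loci:
        if locus not in second.loci:
            continue
        c0 = first.allele_counts(locus)
        c1 = second.allele_counts(locus)
        alleles = sorted(set(c0) | set(c1))
        if not alleles:
            continue
        v0 = np.array([c0.get(a, 0) for a in alleles], dtype=float)
        v1 = np.array([c1.get(a, 0) for a in alleles], dtype=float)
        if v0.sum() == 0 or v1.sum() == 0:
            continue
        x[locus] = v0 / v0.sum()
        y[locus] = v1 / v1.sum()
        cx[locus] = v0
        cy[locus] = v1
    # sample sizes as mean usable individuals per locus
    S0 = float(np.mean([cx[l].sum() / 2.0 for l in cx])) if cx else 0.0
    St = float(np.mean([cy[l].sum() / 2.0 for l in cy])) if cy else 0.0
    return TemporalPairStats(
        x=x, y=y, S0=S0, St=St, t=t, plan=plan, N=N,
        counts_x=cx, counts_y=cy,
        label=f"{first.sample_id}-{second.sample_id}",
    )


@dataclass
class NeEstimate:
    """A point estimate of effective size with a 95% interval.

    ``point``/``ci_low``/``ci_high`` may be +infinity: an infinite estimate
    means the drift signal was at or below the sampling expectation, not
    that the population is infinite. ``below_minimum`` flags LD estimates
    whose inversion discriminant was negative (signal too strong for the
    approximation)."""

    point: float
    ci_low: float
    ci_high: float
    method: str
    corrected_for_overlap: bool = False
    G: float | None = None
    C: float | None = None
    df: float | None = None
    statistic: float | None = None
    below_minimum: bool = False

    def __post_init__(self) -> None:
        if not (self.point > 0 or self.point == INF or self.below_minimum):
            raise ValueError("point estimate must be positive or +infinity")


# ---------------------------------------------------------------------------
# Moments temporal method (Nei-Tajima Fc)


def temporal_fc(pair: TemporalPairStats) -> tuple[float, float]:
    """Multi-locus Nei-Tajima Fc and the chi-square degrees of freedom.

    Per locus, Fc = (1/K) sum_i (x_i - y_i)^2 / (z_i - x_i y_i) with
    z = (x + y)/2 over the K alleles segregating in at least one sample;
    alleles absent from both samples are dropped. Loci are combined by
    weighting with allele counts; df = sum_l (K_l - 1) independent alleles.
    """
    total = 0.0
    weight = 0.0
    df = 0.0
    for locus in pair.x:
        x = pair.x[locus]
        y = pair.y[locus]
        keep = (x + y) > 0
        x, y = x[keep], y[keep]
        if x.size < 2:
            continue
        z = (x + y) / 2.0
        denom = z - x * y
        ok = denom > 0
        if not ok.any():
            continue
        fc_l = float(np.mean(((x - y) ** 2 / denom)[ok]))
        k = int(ok.sum())
        total += k * fc_l
        weight += k
        df += x.size - 1
    if weight == 0:
        raise ValueError("no polymorphic locus shared by both samples")
    return total / weight, df


def _sampling_term(pair: TemporalPairStats) -> float:
    """Expected Fc contribution of sampling under the study design."""
    copies0 = pair.ploidy * pair.S0
    copiest = pair.ploidy * pair.St
    term = 1.0 / copies0 + 1.0 / copiest
    if pair.plan == "I":
        term -= 1.0 / float(pair.N)  # sampled fish may themselves be parents
    return term


def _ne_from_fprime(fprime: float, t: int, ploidy: int) -> float:
    if fprime <= 0:
        return INF
    return t / (ploidy * fprime)


def moments_ne(pair: TemporalPairStats, alpha: float = 0.05) -> NeEstimate:
    """Temporal moments estimator of variance effective size.

    Ne = t / (2 [Fc - 1/(2 S0) - 1/(2 St) (+ 1/N for Plan I)]); a
    non-positive bracket yields +infinity. The CI applies the chi-square
    interval for Fc with df = total independent alleles, propagated through
    the same correction.
    """
    fc, df = temporal_fc(pair)
    samp = _sampling_term(pair)
    point = _ne_from_fprime(fc - samp, pair.t, pair.ploidy)
    lo_f = fc * df / stats.chi2.ppf(1 - alpha / 2, df)
    hi_f = fc * df / stats.chi2.ppf(alpha / 2, df)
    ci_high = _ne_from_fprime(lo_f - samp, pair.t, pair.ploidy)
    ci_low = _ne_from_fprime(hi_f - samp, pair.t, pair.ploidy)
    return NeEstimate(
        point=point, ci_low=ci_low, ci_high=ci_high,
        method="moments", df=df, statistic=fc,
    )


# ---------------------------------------------------------------------------
# Jorde-Ryman Fs


def _fs_raw(x: dict[str, np.ndarray], y: dict[str, np.ndarray]) -> tuple[float, float, float]:
    """Pooled numerator and denominator of Fs across loci (and their ratio)."""
    num = den = 0.0
    for locus in x:
        xv, yv = x[locus], y[locus]
        keep = (xv + yv) > 0
        xv, yv = xv[keep], yv[keep]
        if xv.size < 2:
            continue
        z = (xv + yv) / 2.0
        num += float(np.sum((xv - yv) ** 2))
        den += float(np.sum(z * (1 - z)))
    if den == 0:
        raise ValueError("no usable polymorphism for Fs")
    return num, den, num / den


def temporal_fs(pair: TemporalPairStats) -> float:
    """Raw pooled Jorde-Ryman drift statistic Fs."""
    return _fs_raw(pair.x, pair.y)[2]


def _fs_corrected(fs: float, pair: TemporalPairStats) -> float:
    """Small-sample / finite-census bias correction of Fs.

    Fs' = [Fs (1 - 1/(4 n~)) - 1/n~] / [(1 + Fs/4)(1 - 1/(2 N))], with n~
    the harmonic mean sample size in individuals (diploid data) and N the
    Plan I census size (the factor drops out for Plan II, N -> infinity).
    E[Fs'] ~ t/(2 Ne).
    """
    n_t = pair.harmonic_S
    numer = fs * (1.0 - 1.0 / (4.0 * n_t)) - 1.0 / n_t
    denom = 1.0 + fs / 4.0
    if pair.plan == "I":
        denom *= 1.0 - 1.0 / (2.0 * float(pair.N))
    return numer / denom


def tempofs_ne(pair: TemporalPairStats, alpha: float = 0.05) -> NeEstimate:
    """Temporal Ne from the bias-corrected Fs, jackknifed over loci.

    The delete-one-locus jackknife operates on the corrected Fs scale (the
    numerators and denominators are pooled, so leaving a locus out changes
    both); the normal-theory interval on Fs is then inverted to Ne. A
    single locus yields a point estimate with an undefined (NaN) CI.
    """
    if pair.ploidy != 2:
        raise ValueError("the Fs estimator assumes diploid data")
    _, _, fs = _fs_raw(pair.x, pair.y)
    fsc = _fs_corrected(fs, pair)
    point = _ne_from_fprime(fsc, pair.t, 2)

    loci = [l for l in pair.x if np.count_nonzero(pair.x[l] + pair.y[l]) >= 2]
    if len(loci) < 2:
        return NeEstimate(point=point, ci_low=float("nan"), ci_high=float("nan"),
                          method="tempofs", statistic=fsc)
    pseudo: list[float] = []
    for drop in loci:
        xs = {l: pair.x[l] for l in loci if l != drop}
        ys = {l: pair.y[l] for l in loci if l != drop}
        _, _, fs_i = _fs_raw(xs, ys)
        pseudo.append(_fs_corrected(fs_i, pair))
    m = len(pseudo)
    pseudo_arr = np.asarray(pseudo)
    jk_mean = pseudo_arr.mean()
    jk_var = (m - 1) / m * float(np.sum((pseudo_arr - jk_mean) ** 2))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit * np.sqrt(jk_var)
    ci_high = _ne_from_fprime(fsc - half, pair.t, 2)
    ci_low = _ne_from_fprime(fsc + half, pair.t, 2)
    return NeEstimate(point=point, ci_low=ci_low, ci_high=ci_high,
                      method="tempofs", statistic=fsc)


# ---------------------------------------------------------------------------
# Pseudo-maximum-likelihood temporal estimator


def _wf_transition(grid: np.ndarray, edges: np.ndarray, ne_copies: int) -> np.ndarray:
    """One-generation Wright-Fisher transition matrix on a frequency grid.

    Row i gives the distribution of the next generation's frequency,
    Binomial(ne_copies, grid[i]) / ne_copies, aggregated into grid bins.
    """
    k = np.round(edges * ne_copies).astype(np.int64)  # bin edges in copy counts
    T = np.empty((grid.size, grid.size))
    for i, p in enumerate(grid):
        cdf = stats.binom.cdf(k, ne_copies, p)
        T[i] = np.diff(cdf)
        # counts at the exact lower edge fall in the first bin
        T[i, 0] += stats.binom.pmf(k[0], ne_copies, p)
    T /= T.sum(axis=1, keepdims=True)
    return T


@lru_cache(maxsize=512)
def _wf_transition_power(n_bins: int, ne_copies: int, t: int) -> np.ndarray:
    """t-generation transition matrix, cached across loci and replicates."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])
    return np.linalg.matrix_power(_wf_transition(grid, edges, ne_copies), t)


def mlne_ne(
    pair: TemporalPairStats,
    ne_grid: np.ndarray | None = None,
    n_bins: int = 128,
    alpha: float = 0.05,
) -> NeEstimate:
    """Pseudo-maximum-likelihood temporal Ne on a discretized frequency grid.

    Each allele (vs rest) at each locus contributes a factor
    sum_{p0} Prior(p0) Binom(k0 | copies0, p0) sum_{pt} WF_t(pt | p0, Ne)
    Binom(kt | copiest, pt), with a uniform prior on the p0 grid and
    Wright-Fisher binomial transitions between grid bins. The
    log-pseudo-likelihood is summed over alleles and maximized over
    ``ne_grid``; a maximum on the top grid point is reported as +infinity.
    The CI is the profile-likelihood 2-unit support interval.
    """
    if ne_grid is None:
        ne_grid = np.unique(np.round(np.geomspace(4, 20000, 120)).astype(int))
    ne_grid = np.asarray(sorted(ne_grid))
    if n_bins < 64:
        raise ValueError("frequency grid needs at least 64 bins")
    if not pair.counts_x:
        raise ValueError("likelihood method requires observed allele counts")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])
    copies0 = int(round(pair.ploidy * pair.S0))
    copiest = int(round(pair.ploidy * pair.St))

    if pair.plan == "I" and pair.N is not None and np.isfinite(pair.N):
        # Plan I draws distinct fish from a finite census before
        # reproduction: the sampled copies are hypergeometric, not binomial
        pool = int(round(pair.ploidy * float(pair.N)))

        def obs_pmf(k: int, copies: int) -> np.ndarray:
            good = np.round(grid * pool).astype(np.int64)
            return stats.hypergeom.pmf(k, pool, good, copies)

    else:

        def obs_pmf(k: int, copies: int) -> np.ndarray:
            return stats.binom.pmf(k, copies, grid)

    # per-allele observation vectors on the grid
    obs0: list[np.ndarray] = []
    obst: list[np.ndarray] = []
    for locus in pair.counts_x:
        cx = pair.counts_x[locus]
        cy = pair.counts_y[locus]
        n0 = int(cx.sum())
        nt = int(cy.sum())
        if n0 == 0 or nt == 0:
            raise ValueError(f"locus {locus}: zero sampled copies")
        keep = (cx + cy) > 0
        if keep.sum() < 2:
            continue
        for k0, kt in zip(cx[keep], cy[keep]):
            obs0.append(obs_pmf(int(k0), n0))
            obst.append(obs_pmf(int(kt), nt))
    if not obs0:
        raise ValueError("no usable polymorphism for the likelihood method")
    O0 = np.asarray(obs0)
    Ot = np.asarray(obst)

    loglik = np.empty(ne_grid.size)
    for j, ne in enumerate(ne_grid):
        T = _wf_transition_power(n_bins, int(round(pair.ploidy * ne)), pair.t)
        # factor per allele: (1/n_bins) * o0 @ T @ ot
        lik = np.einsum("ag,gh,ah->a", O0, T, Ot) / n_bins
        loglik[j] = float(np.sum(np.log(np.maximum(lik, 1e-300))))

    jmax = int(np.argmax(loglik))
    support = loglik >= loglik[jmax] - 2.0
    ci_low = float(ne_grid[support][0])
    ci_high = float(ne_grid[support][-1]) if not support[-1] else INF
    point = INF if jmax == ne_grid.size - 1 else float(ne_grid[jmax])
    return NeEstimate(point=point, ci_low=ci_low, ci_high=ci_high, method="mlne",
                      statistic=float(loglik[jmax]))


# ---------------------------------------------------------------------------
# Linkage-disequilibrium single-sample method


@dataclass
class LDStats:
    """Summary of the Burrows composite disequilibrium screening."""

    Pcrit: float
    S: float
    r2_mean: float
    r2_expected: float
    r2_prime: float
    n_comparisons: int


def _expected_r2(S: float) -> float:
    """Sampling expectation of r^2 for random mating (empirical fits)."""
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def _invert_r2(r2p: float, S: float) -> tuple[float, bool]:
    """Random-mating inversion of adjusted r^2 to Ne."""
    if r2p <= 0:
        return INF, False
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        third = 1.0 / 3.0
    else:
        disc = 1.0 / 9.0 - 2.08 * r2p
        third = 0.308
    if disc < 0:
        return 0.0, True  # below the estimable minimum
    ne = (third + np.sqrt(disc)) / (2.0 * r2p)
    if ne <= 0:
        return 0.0, True
    return float(ne), False


def _r2_comparisons(table: GenotypeTable, Pcrit: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All allele-pair r^2 values across locus pairs after Pcrit screening.

    Returns (r2 values, weights = usable n, locus-pair index per value).
    The Burrows composite disequilibrium uses allele dosages X in {0,1,2}:
    Delta = cov(X_A, X_B)/2 with the n/(n-1) covariance, and
    r^2 = Delta^2 / (p_A(1-p_A) p_B(1-p_B)).
    """
    loci = table.loci
    dosages: dict[str, tuple[np.ndarray, list[np.ndarray]]] = {}
    for locus in loci:
        geno = table.genotype_matrix(locus)
        usable = geno[:, 0] != 0
        copies = np.concatenate([geno[usable, 0], geno[usable, 1]])
        if copies.size == 0:
            continue
        alleles, counts = np.unique(copies, return_counts=True)
        freqs = counts / copies.size
        keep = (freqs >= Pcrit) & (freqs <= 1 - Pcrit)
        if keep.sum() == 0:
            continue
        dos = [(geno == a).sum(axis=1).astype(float) for a in alleles[keep]]
        dosages[locus] = (usable, dos)
    names = [l for l in loci if l in dosages]
    r2s: list[float] = []
    ws: list[float] = []
    pair_idx: list[int] = []
    pair_no = -1
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair_no += 1
            ua, dos_a = dosages[names[i]]
            ub, dos_b = dosages[names[j]]
            both = ua & ub
            n = int(both.sum())
            if n < 10:
                continue
            for xa in dos_a:
                for xb in dos_b:
                    x = xa[both]
                    yv = xb[both]
                    pa = x.mean() / 2.0
                    pb = yv.mean() / 2.0
                    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                        continue
                    cov = float(np.sum((x - x.mean()) * (yv - yv.mean()))) / (n - 1)
                    delta = cov / 2.0
                    r2 = delta**2 / (pa * (1 - pa) * pb * (1 - pb))
                    r2s.append(r2)
                    ws.append(float(n))
                    pair_idx.append(pair_no)
    return np.asarray(r2s), np.asarray(ws), np.asarray(pair_idx)


def ld_ne(
    table: GenotypeTable,
    Pcrit: float = 0.02,
    mating: str = "random",
    alpha: float = 0.05,
) -> tuple[NeEstimate, LDStats]:
    """Single-sample Ne from linkage disequilibrium (Burrows composite r^2).

    Alleles rarer than ``Pcrit`` are screened out; the weighted mean r^2
    over all allele pairs across locus pairs is adjusted by the sampling
    expectation E[r^2 | S] at the harmonic mean sample size S and inverted
    under random mating. r2' <= 0 gives +infinity. The CI is a delete-one
    locus-pair jackknife on the r^2-mean scale.
    """
    if mating != "random":
        raise ValueError("only the random-mating inversion is implemented")
    if table.n_individuals < 10:
        raise ValueError("need at least 10 individuals")
    r2s, ws, pair_idx = _r2_comparisons(table, Pcrit)
    if r2s.size == 0 or np.unique(pair_idx).size < 1:
        raise ValueError("fewer than 2 polymorphic loci after screening")
    S = float(r2s.size / np.sum(1.0 / ws))  # harmonic mean sample size
    r2_mean = float(np.average(r2s, weights=ws))
    exp = _expected_r2(S)
    r2p = r2_mean - exp
    point, below = _invert_r2(r2p, S)

    # delete-one locus-pair jackknife
    pairs = np.unique(pair_idx)
    ci_low = ci_high = float("nan")
    if pairs.size >= 2:
        pseudo = []
        for p in pairs:
            keep = pair_idx != p
            m = float(np.average(r2s[keep], weights=ws[keep]))
            Sk = float(r2s[keep].size / np.sum(1.0 / ws[keep]))
            pseudo.append(m - _expected_r2(Sk))
        arr = np.asarray(pseudo)
        m_ = arr.mean()
        jk_var = (pairs.size - 1) / pairs.size * float(np.sum((arr - m_) ** 2))
        half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(jk_var)
        hi_ne, _ = _invert_r2(r2p - half, S)
        lo_ne, lo_below = _invert_r2(r2p + half, S)
        ci_high = hi_ne
        ci_low = lo_ne if not lo_below else 0.0
    est = NeEstimate(point=point, ci_low=ci_low, ci_high=ci_high,
                     method="ld", statistic=r2_mean, below_minimum=below)
    stats_out = LDStats(Pcrit=Pcrit, S=S, r2_mean=r2_mean, r2_expected=exp,
                        r2_prime=r2p, n_comparisons=int(r2s.size))
    return est, stats_out


# ---------------------------------------------------------------------------
# Haploid moments (mtDNA, female effective size)


def haploid_moments_nef(pair: TemporalPairStats, alpha: float = 0.05) -> NeEstimate:
    """Temporal moments estimator for the haploid (maternal) genome.

    Nef = t / (Fc - 1/S0 - 1/St) with sample sizes in sequences; a
    non-positive bracket yields +infinity.
    """
    if pair.ploidy != 1:
        raise ValueError("haploid estimator requires ploidy=1 data")
    if pair.S0 < 2 or pair.St < 2:
        raise ValueError("need at least 2 sequences per sample")
    fc, df = temporal_fc(pair)
    samp = 1.0 / pair.S0 + 1.0 / pair.St
    if pair.plan == "I":
        samp -= 1.0 / float(pair.N)
    point = _ne_from_fprime(fc - samp, pair.t, 1)
    lo_f = fc * df / stats.chi2.ppf(1 - alpha / 2, df)
    hi_f = fc * df / stats.chi2.ppf(alpha / 2, df)
    ci_high = _ne_from_fprime(lo_f - samp, pair.t, 1)
    ci_low = _ne_from_fprime(hi_f - samp, pair.t, 1)
    return NeEstimate(point=point, ci_low=ci_low, ci_high=ci_high,
                      method="haploid_moments", df=df, statistic=fc)


# ---------------------------------------------------------------------------
# Overlapping-generation correction and broodstock Ne


def overlap_correction(estimate: NeEstimate, C: float, G: float) -> NeEstimate:
    """Correct a consecutive-year estimate for overlapping generations.

    Applies Ne_adj = (C / G) * Ne with generation length G (years) and the
    correction factor C of the age-structured adjustment; infinities map to
    infinities and CI bounds scale by the same factor.
    """
    if C <= 0 or G <= 0:
        raise ValueError("C and G must be positive")
    factor = C / G

    def scale(v: float) -> float:
        return v if v == INF or np.isnan(v) else v * factor

    return replace(
        estimate,
        point=scale(estimate.point),
        ci_low=scale(estimate.ci_low),
        ci_high=scale(estimate.ci_high),
        corrected_for_overlap=True,
        G=G,
        C=C,
    )


def broodstock_ne(Nm: int, Nf: int) -> float:
    """Sex-ratio effective size of a breeding lot: 4 Nm Nf / (Nm + Nf)."""
    if Nm < 1 or Nf < 1:
        raise ValueError("both sexes need at least one breeder")
    return 4.0 * Nm * Nf / (Nm + Nf)
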