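"""Hardy-Weinberg exact tests, inter-locus disequilibrium tests, and
sequential Bonferroni control.

The HWE test is the conditional exact test: given the observed allele
counts, the probability of a diploid genotype array under random union of
gametes is

    P(array | allele counts) = n! * prod_j a_j! * 2^h / ((2n)! * prod_{i<=j} f_ij!)

with n individuals, a_j allele counts, h heterozygotes, and f_ij genotype
counts. The p-value is the total probability of arrays no more probable
than the one observed (inclusive ties). Small tables are enumerated
exactly; larger ones are estimated by Monte Carlo shuffling of gene copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np

from .popdata import GenotypeTable

__all__ = ["TestResult", "hwe_exact_test", "pairwise_ld_test", "sequential_bonferroni"]

_LOG2 = log(2.0)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_reps: int
    method: str


def _log_array_prob(counts: dict[tuple[int, int], int]) -> float:
    """Log conditional probability of a genotype-count array given alleles."""
    n = sum(counts.values())
    allele: dict[int, int] = {}
    h = 0
    for (a, b), c in counts.items():
        allele[a] = allele.get(a, 0) + c
        allele[b] = allele.get(b, 0) + c
        if a != b:
            h += c
    lp = lgamma(n + 1) - lgamma(2 * n + 1) + h * _LOG2
    for cnt in allele.values():
        lp += lgamma(cnt + 1)
    for c in counts.values():
        lp -= lgamma(c + 1)
    return lp


def _genotype_counts(genotypes: np.ndarray) -> dict[tuple[int, int], int]:
    out: dict[tuple[int, int], int] = {}
    for a, b in genotypes:
        key = (int(min(a, b)), int(max(a, b)))
        out[key] = out.get(key, 0) + 1
    return out


def _enumerate_pvalue(allele_counts: dict[int, int], observed_lp: float) -> float:
    """Exact p by recursive enumeration of genotype arrays with the given
    allele counts. Feasible for small samples / few alleles."""
    alleles = sorted(allele_counts)
    pairs = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]
    total_copies = sum(allele_counts.values())
    n = total_copies // 2
    num = 0.0
    den = 0.0

    def rec(idx: int, remaining: dict[int, int], counts: dict, n_left: int) -> None:
        nonlocal num, den
        if idx == len(pairs):
            if n_left == 0 and all(v == 0 for v in remaining.values()):
                lp = _log_array_prob(counts) if counts else 0.0
                p = np.exp(lp)
                den += p
                if lp <= observed_lp + 1e-9:
                    num += p
            return
        a, b = pairs[idx]
        if a == b:
            maxc = min(remaining[a] // 2, n_left)
        else:
            maxc = min(remaining[a], remaining[b], n_left)
        for c in range(maxc + 1):
            if c:
                counts[(a, b)] = c
                remaining[a] -= c if a == b else c
                if a == b:
                    remaining[a] -= c
                else:
                    remaining[b] -= c
            rec(idx + 1, remaining, counts, n_left - c)
            if c:
                if a == b:
                    remaining[a] += 2 * c
                else:
                    remaining[a] += c
                    remaining[b] += c
                del counts[(a, b)]

    rec(0, dict(allele_counts), {}, n)
    return float(num / den)


def hwe_exact_test(
    genotypes: np.ndarray | GenotypeTable,
    locus: str | None = None,
    mode: str = "auto",
    n_shuffles: int = 10000,
    seed: int | np.random.Generator = 0,
    randomized: bool = False,
) -> TestResult:
    """Conditional exact test of Hardy-Weinberg proportions at one locus.

    ``genotypes`` is an (n, 2) allele-label array (or a table plus locus
    name); missing calls (0, 0) are dropped. ``mode`` is 'enumerate', 'mc',
    or 'auto' (enumerate when the array space is small). The MC estimate
    shuffles the 2n gene copies into random pairs and counts arrays with
    conditional probability <= observed (inclusive), an unbiased estimate
    of the exact p.

    ``randomized=True`` returns the randomized (tie-broken) p-value,
    P(T < t) + U * P(T = t): exactly uniform under the null, which is the
    correct quantity for calibration diagnostics of a discrete test. The
    default inclusive p is the one to report and is conservative.
    """
    if isinstance(genotypes, GenotypeTable):
        if locus is None:
            raise ValueError("locus name required with a GenotypeTable")
        genotypes = genotypes.genotype_matrix(locus)
    geno = np.asarray(genotypes, dtype=np.int64)
    geno = geno[geno[:, 0] != 0]
    n = geno.shape[0]
    if n < 2:
        raise ValueError("need at least 2 usable individuals")
    copies = np.concatenate([geno[:, 0], geno[:, 1]])
    alleles, counts = np.unique(copies, return_counts=True)
    if alleles.size < 2:
        return TestResult(statistic=0.0, p_value=1.0, n_reps=0, method="monomorphic")

    obs_counts = _genotype_counts(geno)
    obs_lp = _log_array_prob(obs_counts)
    allele_counts = {int(a): int(c) for a, c in zip(alleles, counts)}
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if mode == "auto":
        k = alleles.size
        mode = "enumerate" if (k == 2 and n <= 500) or (k <= 4 and n <= 12) else "mc"

    if mode == "enumerate":
        if alleles.size == 2:
            # enumerate over heterozygote count only
            a1, a2 = (int(a) for a in alleles)
            n1 = allele_counts[a1]
            num = num_strict = den = 0.0
            for het in range(n1 % 2, min(n1, allele_counts[a2]) + 1, 2):
                cts = {}
                if (n1 - het) // 2:
                    cts[(a1, a1)] = (n1 - het) // 2
                if het:
                    cts[(a1, a2)] = het
                if (allele_counts[a2] - het) // 2:
                    cts[(a2, a2)] = (allele_counts[a2] - het) // 2
                lp = _log_array_prob(cts)
                p = float(np.exp(lp))
                den += p
                if lp <= obs_lp + 1e-9:
                    num += p
                    if lp < obs_lp - 1e-9:
                        num_strict += p
            pv = num / den
            if randomized:
                pv = (num_strict + rng.random() * (num - num_strict)) / den
            return TestResult(statistic=obs_lp, p_value=pv, n_reps=0, method="enumerate")
        if randomized:
            raise ValueError("randomized p is implemented for the biallelic/MC paths")
        p = _enumerate_pvalue(allele_counts, obs_lp)
        return TestResult(statistic=obs_lp, p_value=p, n_reps=0, method="enumerate")

    if mode != "mc":
        raise ValueError("mode must be 'auto', 'enumerate' or 'mc'")
    hits_le = 0
    hits_eq = 0
    pool = copies.copy()
    for _ in range(n_shuffles):
        rng.shuffle(pool)
        arr = pool.reshape(n, 2)
        lp = _log_array_prob(_genotype_counts(arr))
        if lp <= obs_lp + 1e-9:
            hits_le += 1
            if lp >= obs_lp - 1e-9:
                hits_eq += 1
    if randomized:
        # permutation-style randomized p: exactly uniform under the null
        pv = (hits_le - hits_eq + rng.random() * (hits_eq + 1)) / (n_shuffles + 1)
    else:
        pv = hits_le / n_shuffles
    return TestResult(statistic=obs_lp, p_value=pv, n_reps=n_shuffles, method="mc")


# ---------------------------------------------------------------------------
# Inter-locus (linkage) disequilibrium


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for independence in a contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def _geno_codes(geno: np.ndarray) -> np.ndarray:
    """Unordered genotype code per individual (missing -> -1)."""
    lo = np.minimum(geno[:, 0], geno[:, 1])
    hi = np.maximum(geno[:, 0], geno[:, 1])
    codes = lo * 10000 + hi
    codes[geno[:, 0] == 0] = -1
    return codes


def pairwise_ld_test(
    samples: GenotypeTable | list[GenotypeTable],
    locus_pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> TestResult:
    """Permutation test of genotypic association between two loci.

    The statistic is the G (log-likelihood-ratio) of the genotype-by-
    genotype contingency table; permutations shuffle one locus's genotypes
    across individuals within each sample, and the global statistic sums G
    over samples. p = fraction of permutations with G >= observed.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if isinstance(samples, GenotypeTable):
        samples = [samples]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    la, lb = locus_pair
    per_sample: list[tuple[np.ndarray, np.ndarray]] = []
    for t in samples:
        ca = _geno_codes(t.genotype_matrix(la))
        cb = _geno_codes(t.genotype_matrix(lb))
        ok = (ca >= 0) & (cb >= 0)
        if ok.sum() >= 2:
            per_sample.append((ca[ok], cb[ok]))
    if not per_sample:
        raise ValueError("fewer than 2 usable individuals in every sample")

    def total_g(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
        g = 0.0
        for ca, cb in pairs:
            ua, ia = np.unique(ca, return_inverse=True)
            ub, ib = np.unique(cb, return_inverse=True)
            tab = np.zeros((ua.size, ub.size))
            np.add.at(tab, (ia, ib), 1.0)
            g += _g_statistic(tab)
        return g

    observed = total_g(per_sample)
    ge = 0
    for _ in range(n_perm):
        permuted = [(ca, cb[rng.permutation(cb.size)]) for ca, cb in per_sample]
        if total_g(permuted) >= observed - 1e-12:
            ge += 1
    return TestResult(statistic=observed, p_value=ge / n_perm, n_reps=n_perm, method="permutation_G")


def sequential_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm's sequentially rejective Bonferroni procedure.

    Sort p ascending; reject p_(i) while p_(i) <= alpha / (k - i + 1)
    (1-based i), stopping at the first failure. Returns a boolean rejection
    flag per input position.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    order = np.argsort(p, kind="stable")
    k = p.size
    reject = np.zeros(k, dtype=bool)
    for i, idx in enumerate(order, start=1):
        if p[idx] <= alpha / (k - i + 1):
            reject[idx] = True
        else:
            break
    return reject
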