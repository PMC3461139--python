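"""Weir-Cockerham F-statistics and hierarchical AMOVA with permutation tests.

Both estimators are method-of-moments solutions of a nested random-effects
ANOVA. For diploid data the observations are gene copies nested in
individuals, nested in samples (and optionally in groups of samples); the
within-individual component captures departures from random union of
gametes, so the two-level solution reproduces the Weir-Cockerham theta
exactly. For haploid data the ANOVA is expressed through squared
inter-haplotype distances (identity by default), giving Phi-statistics.

Negative variance components are reported as estimated, never truncated,
and fixation indices are computed from the raw components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popdata import GenotypeTable, HaplotypeTable

__all__ = ["AmovaResult", "weir_cockerham_fst", "amova_three_level"]


# ---------------------------------------------------------------------------
# Nested ANOVA engine


def _codes(*label_arrays: np.ndarray) -> np.ndarray:
    """Fuse several label arrays into one integer cell code (nested cells)."""
    stacked = np.stack(label_arrays, axis=1)
    _, codes = np.unique(stacked, axis=0, return_inverse=True)
    return codes


def _nested_ss(y: np.ndarray, partitions: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sums of squares, df, and expected-SS coefficient matrix.

    ``y`` is an (N, K) one-hot (or numeric) observation matrix;
    ``partitions`` lists the nesting levels coarse-to-fine as integer label
    arrays per observation (the error level of singleton cells is
    implicit). Returns (SS, df, C), one row per level including error; the
    moment equations are E[SS] = C @ sigma2, with C upper triangular.
    """
    N = y.shape[0]
    L = len(partitions)
    level_codes: list[np.ndarray] = [np.zeros(N, dtype=np.int64)]
    for l in range(L):
        level_codes.append(_codes(*partitions[: l + 1]))
    level_codes.append(np.arange(N, dtype=np.int64))

    sizes: list[np.ndarray] = []
    T = np.empty(L + 2)
    ncells = np.empty(L + 2, dtype=np.int64)
    for l, codes in enumerate(level_codes):
        k = int(codes.max()) + 1
        n = np.bincount(codes, minlength=k).astype(float)
        s2 = 0.0
        for j in range(y.shape[1]):
            sums = np.bincount(codes, weights=y[:, j], minlength=k)
            s2 += float(np.sum(sums**2 / n))
        sizes.append(n)
        T[l] = s2
        ncells[l] = k

    SS = T[1:] - T[:-1]
    df = (ncells[1:] - ncells[:-1]).astype(float)

    def K(l: int, m: int) -> float:
        # sum over cells e of the finer of (l, m): n_e^2 / n of the l-cell holding e
        f = max(l, m)
        codes_f, codes_l = level_codes[f], level_codes[l]
        n_f, n_l = sizes[f], sizes[l]
        order = np.argsort(codes_f, kind="stable")
        starts = np.searchsorted(codes_f[order], np.arange(ncells[f]))
        parent = codes_l[order[starts]]
        return float(np.sum(n_f**2 / n_l[parent]))

    nlev = L + 1
    C = np.zeros((nlev, nlev))
    for l in range(1, L + 2):
        for m in range(l, L + 2):
            C[l - 1, m - 1] = K(l, m) - K(l - 1, m)
    return SS, df, C


# ---------------------------------------------------------------------------
# Shared diploid data preparation


def _one_hot(labels: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(labels, return_inverse=True)
    y = np.zeros((labels.size, uniq.size))
    y[np.arange(labels.size), inv] = 1.0
    return y


class _DiploidData:
    """Per-locus copy-level arrays with stable global individual indices."""

    def __init__(self, samples: list[GenotypeTable]):
        self.loci = samples[0].loci
        for t in samples:
            if t.loci != self.loci:
                raise ValueError("samples must share the same locus list")
        self.n_samples = len(samples)
        offsets = np.cumsum([0] + [t.n_individuals for t in samples])
        self.n_individuals = int(offsets[-1])
        # home sample of each global individual
        self.pop_of_ind = np.repeat(np.arange(self.n_samples), [t.n_individuals for t in samples])
        self.per_locus: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for locus in self.loci:
            inds: list[int] = []
            alleles: list[int] = []
            for p, t in enumerate(samples):
                geno = t.genotype_matrix(locus)
                for i, (a, b) in enumerate(geno):
                    if a == 0:
                        continue
                    g = int(offsets[p] + i)
                    inds += [g, g]
                    alleles += [int(a), int(b)]
            arr = np.asarray(alleles, dtype=np.int64)
            if arr.size and np.unique(arr).size >= 2:
                self.per_locus[locus] = (np.asarray(inds, dtype=np.int64), _one_hot(arr))

    def components(
        self,
        group_of_pop: np.ndarray | None,
        pop_of_ind: np.ndarray | None = None,
    ) -> np.ndarray:
        """Summed variance components across loci.

        Without groups: (a, b, c) = among samples / among individuals
        within samples / within individuals. With groups: (a, b, b_i, c)
        adding the among-groups level on top.
        """
        pop = self.pop_of_ind if pop_of_ind is None else pop_of_ind
        total = None
        for ind, y in self.per_locus.values():
            pop_of_copy = pop[ind]
            parts = [pop_of_copy, ind]
            if group_of_pop is not None:
                parts = [group_of_pop[pop_of_copy]] + parts
            SS, _, Cmat = _nested_ss(y, parts)
            sigma = np.linalg.solve(Cmat, SS)
            total = sigma if total is None else total + sigma
        if total is None:
            raise ValueError("all loci monomorphic; components undefined")
        return total


def weir_cockerham_fst(samples: list[GenotypeTable]) -> tuple[dict[str, float], float]:
    """Weir-Cockerham theta per locus and overall (ratio of summed components).

    Variance components a (among samples), b (among individuals within
    samples) and c (within individuals) are estimated per locus by the
    nested ANOVA moment equations; overall theta = sum a / sum (a + b + c).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    data = _DiploidData(samples)
    per_locus: dict[str, float] = {}
    total = np.zeros(3)
    for locus, (ind, y) in data.per_locus.items():
        SS, _, Cmat = _nested_ss(y, [data.pop_of_ind[ind], ind])
        sigma = np.linalg.solve(Cmat, SS)
        if sigma.sum() != 0:
            per_locus[locus] = sigma[0] / sigma.sum()
        total += sigma
    if not per_locus:
        raise ValueError("all loci monomorphic; theta undefined")
    return per_locus, float(total[0] / total.sum())


# ---------------------------------------------------------------------------
# Three-level AMOVA


@dataclass
class AmovaResult:
    """Hierarchical variance components and fixation indices.

    Components: among groups (sigma2_a), among samples within groups
    (sigma2_b), within samples (sigma2_w; for diploid data this lumps the
    among-individual and within-individual components). For haploid
    distance mode the indices are the Phi-statistics on the squared
    distance scale.
    """

    sigma2_a: float
    sigma2_b: float
    sigma2_w: float
    F_CT: float
    F_SC: float
    F_ST: float
    p_CT: float | None = None
    p_SC: float | None = None
    p_ST: float | None = None
    n_permutations: int = 0
    mode: str = "diploid_freq"


def _haploid_ssd(dist2: np.ndarray, codes: np.ndarray) -> float:
    """Sum over cells of (sum_{i<j in cell} d2_ij) / n_cell."""
    total = 0.0
    for cell in np.unique(codes):
        idx = np.where(codes == cell)[0]
        if idx.size < 2:
            continue
        sub = dist2[np.ix_(idx, idx)]
        total += float(sub[np.triu_indices(idx.size, k=1)].sum()) / idx.size
    return total


def _haploid_components(
    dist2: np.ndarray, pop: np.ndarray, group_of_pop: np.ndarray
) -> np.ndarray:
    """(a, b, within) components from squared distances over haploid copies."""
    N = pop.size
    grp = group_of_pop[pop]
    W0 = _haploid_ssd(dist2, np.zeros(N, dtype=np.int64))
    W1 = _haploid_ssd(dist2, grp)
    W2 = _haploid_ssd(dist2, _codes(grp, pop))
    SS = np.array([W0 - W1, W1 - W2, W2])
    dummy = np.ones((N, 1))
    _, _, Cmat = _nested_ss(dummy, [grp, pop])
    # the SSD decomposition shares the nested ANOVA size coefficients
    return np.linalg.solve(Cmat, SS)


def _indices(a: float, b: float, w: float) -> tuple[float, float, float]:
    tot = a + b + w
    fct = a / tot if tot != 0 else float("nan")
    fsc = b / (b + w) if (b + w) != 0 else float("nan")
    fst = (a + b) / tot if tot != 0 else float("nan")
    return fct, fsc, fst  # F_CT, F_SC, F_ST


def amova_three_level(
    samples: list[GenotypeTable] | list[HaplotypeTable],
    groups: dict[str, str] | list[str],
    mode: str = "diploid_freq",
    distance: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AmovaResult:
    """Three-level AMOVA: among groups / among samples within groups / within.

    ``groups`` maps sample_id (or lists, in sample order) to a group label;
    every group needs at least one sample. ``mode='diploid_freq'`` runs the
    allele-indicator ANOVA on microsatellite gene copies (retaining the
    individual level internally); ``mode='haploid_distance'`` runs the
    squared-distance form on haplotype copies, with an identity distance by
    default or a user-supplied squared-distance matrix over the sorted
    haplotype alphabet (e.g. substitution counts).

    Permutation schemes: F_CT permutes whole samples among groups; F_SC
    permutes individuals among samples within groups; F_ST permutes
    individuals among all samples. p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(groups, dict):
        group_labels = [groups[t.sample_id] for t in samples]
    else:
        group_labels = list(groups)
    if len(group_labels) != len(samples):
        raise ValueError("one group label per sample required")
    uniq_groups, group_of_pop = np.unique(group_labels, return_inverse=True)
    if uniq_groups.size < 2:
        raise ValueError("need at least 2 groups")

    if mode == "diploid_freq":
        data = _DiploidData(samples)  # type: ignore[arg-type]
        pop_of_ind_obs = data.pop_of_ind

        def components(gop: np.ndarray, pop_of_ind: np.ndarray | None) -> np.ndarray:
            a, b, bi, c = data.components(gop, pop_of_ind)
            return np.array([a, b, bi + c])

    elif mode == "haploid_distance":
        labels: list[str] = []
        pop_list: list[int] = []
        for p, t in enumerate(samples):
            for h in t.haplotype:  # type: ignore[union-attr]
                if h is None:
                    continue
                labels.append(h)
                pop_list.append(p)
        alphabet = sorted(set(labels))
        code = {h: i for i, h in enumerate(alphabet)}
        hap_codes = np.asarray([code[h] for h in labels])
        pop_of_ind_obs = np.asarray(pop_list, dtype=np.int64)
        if distance is None:
            d2 = 1.0 - np.eye(len(alphabet))
        else:
            d2 = np.asarray(distance, dtype=float)
            if d2.shape != (len(alphabet), len(alphabet)):
                raise ValueError("distance matrix shape does not match haplotype alphabet")
        dist2 = d2[np.ix_(hap_codes, hap_codes)]

        def components(gop: np.ndarray, pop_of_ind: np.ndarray | None) -> np.ndarray:
            pop = pop_of_ind_obs if pop_of_ind is None else pop_of_ind
            return _haploid_components(dist2, pop, gop)

    else:
        raise ValueError("mode must be 'diploid_freq' or 'haploid_distance'")

    a, b, w = components(group_of_pop, None)
    fct, fsc, fst = _indices(a, b, w)

    p_ct = p_sc = p_st = None
    if n_perm > 0:
        ge_ct = ge_sc = ge_st = 0
        n_samples = len(samples)
        for _ in range(n_perm):
            gop = group_of_pop[rng.permutation(n_samples)]
            c1 = components(gop, None)
            if _indices(*c1)[0] >= fct:
                ge_ct += 1
            perm_all = pop_of_ind_obs[rng.permutation(pop_of_ind_obs.size)]
            c2 = components(group_of_pop, perm_all)
            if _indices(*c2)[2] >= fst:
                ge_st += 1
            perm_within = pop_of_ind_obs.copy()
            for g in range(uniq_groups.size):
                mask = group_of_pop[pop_of_ind_obs] == g
                vals = perm_within[mask]
                perm_within[mask] = vals[rng.permutation(vals.size)]
            c3 = components(group_of_pop, perm_within)
            if _indices(*c3)[1] >= fsc:
                ge_sc += 1
        p_ct = (ge_ct + 1) / (n_perm + 1)
        p_sc = (ge_sc + 1) / (n_perm + 1)
        p_st = (ge_st + 1) / (n_perm + 1)

    return AmovaResult(
        sigma2_a=float(a), sigma2_b=float(b), sigma2_w=float(w),
        F_CT=float(fct), F_SC=float(fsc), F_ST=float(fst),
        p_CT=p_ct, p_SC=p_sc, p_ST=p_st,
        n_permutations=n_perm, mode=mode,
    )
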