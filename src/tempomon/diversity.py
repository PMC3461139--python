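"""Per-sample genetic diversity metrics for diploid and haploid data.

Covers unbiased gene diversity (haploid) and unbiased expected
heterozygosity (diploid), observed heterozygosity, rarefaction of allelic /
haplotype richness, the Weir-Cockerham within-sample inbreeding coefficient
F_IS, and a resampling-based correction of diversity to a common sample
size, the approach used in long-term monitoring studies when sampling
effort varies among years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .popdata import GenotypeTable, HaplotypeTable, frequencies_from_table

__all__ = [
    "DiversityStats",
    "CorrectedDiversity",
    "unbiased_gene_diversity",
    "expected_het_unbiased",
    "observed_het",
    "rarefied_richness",
    "fis_within",
    "resample_corrected",
    "haplotype_inventory",
    "sample_diversity",
]


def unbiased_gene_diversity(counts: Sequence[int] | dict, n: int | None = None) -> float:
    """Unbiased gene (haplotype) diversity h = n/(n-1) * (1 - sum p_i^2).

    ``counts`` are haplotype counts out of ``n`` sequences; if ``n`` is None
    it is taken as the count total. The n/(n-1) factor corrects the plug-in
    estimator's downward small-sample bias.
    """
    freqs, total = frequencies_from_table(counts)
    n = total if n is None else n
    if n < 2:
        raise ValueError("gene diversity requires at least 2 sequences")
    return float(n / (n - 1) * (1.0 - np.sum(freqs**2)))


def expected_het_unbiased(allele_counts: Sequence[int] | dict) -> float:
    """Unbiased expected heterozygosity from diploid gene-copy counts.

    With 2n gene copies, He = 2n/(2n-1) * (1 - sum p_i^2); the correction is
    identical in form to the haploid one, applied on the gene-copy scale.
    """
    freqs, copies = frequencies_from_table(allele_counts)
    if copies < 2:
        raise ValueError("need at least 2 gene copies")
    return float(copies / (copies - 1) * (1.0 - np.sum(freqs**2)))


def observed_het(table: GenotypeTable, locus: str) -> float:
    """Proportion of heterozygous individuals among usable calls at a locus."""
    geno = table.genotype_matrix(locus)
    usable = geno[:, 0] != 0
    if not usable.any():
        raise ValueError(f"no usable calls at locus {locus}")
    het = geno[usable, 0] != geno[usable, 1]
    return float(het.mean())


def rarefied_richness(counts: Sequence[int] | dict, g: int) -> float:
    """Expected number of distinct alleles in a random subsample of g copies.

    Hypergeometric rarefaction: sum_i [1 - C(n - n_i, g) / C(n, g)] over
    observed allele counts n_i with n = sum n_i. Equals the observed count
    at g = n, and 1.0 at g = 1.
    """
    if isinstance(counts, dict):
        counts = list(counts.values())
    arr = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    n = int(arr.sum())
    if not 1 <= g <= n:
        raise ValueError(f"rarefaction size g={g} outside [1, {n}]")

    def log_choose(a: np.ndarray | int, b: int) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    with np.errstate(invalid="ignore"):
        # P(allele i absent from the subsample) = C(n - n_i, g) / C(n, g)
        absent = np.where(
            n - arr >= g,
            np.exp(log_choose(n - arr, g) - log_choose(n, g)),
            0.0,
        )
    return float(np.sum(1.0 - absent))


# ---------------------------------------------------------------------------
# F_IS (Weir-Cockerham within-sample estimator)


def _wc_within_components(table: GenotypeTable, locus: str) -> tuple[float, float] | None:
    """Per-locus Weir-Cockerham (b, c) components summed over alleles.

    b is the among-individual, c the within-individual (gametic) component;
    the within-sample inbreeding coefficient is f = b / (b + c). Returns
    None for monomorphic or unusable loci.
    """
    geno = table.genotype_matrix(locus)
    geno = geno[geno[:, 0] != 0]
    n = geno.shape[0]
    if n < 2:
        return None
    alleles = np.unique(geno)
    if alleles.size < 2:
        return None
    b_sum = 0.0
    c_sum = 0.0
    for a in alleles:
        x = (geno == a).sum(axis=1)  # 0, 1 or 2 copies per individual
        p = x.mean() / 2.0
        h = (x == 1).mean()  # observed heterozygote frequency for allele a
        b = n / (n - 1.0) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
        c = h / 2.0
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def fis_within(table: GenotypeTable) -> tuple[dict[str, float], float]:
    """Weir-Cockerham F_IS per polymorphic locus and the weighted mean.

    The multi-locus mean is the ratio of summed variance components
    (sum b / sum (b + c)), the weighting used by FSTAT's "weighted"
    inbreeding coefficient; monomorphic loci are excluded.
    """
    per_locus: dict[str, float] = {}
    B = C = 0.0
    for locus in table.loci:
        comps = _wc_within_components(table, locus)
        if comps is None:
            continue
        b, c = comps
        if b + c != 0:
            per_locus[locus] = b / (b + c)
        B += b
        C += c
    if not per_locus:
        raise ValueError("no polymorphic locus available for F_IS")
    return per_locus, B / (B + C)


# ---------------------------------------------------------------------------
# Summary containers


@dataclass
class DiversityStats:
    """Uncorrected per-sample diversity summary."""

    sample_id: str
    He: dict[str, float]
    Ho: dict[str, float]
    A: dict[str, int]
    n: dict[str, int]
    He_mean: float
    Ho_mean: float
    A_mean: float
    fis: float | None = None
    h: float | None = None
    n_haplotypes: int | None = None


@dataclass
class CorrectedDiversity:
    """Diversity corrected to a common sample size by repeated subsampling.

    Hec/Hoc/Nac are means over ``B`` random subsamples of ``n_star``
    individuals (across-locus mean per subsample, then mean over
    subsamples); the CIs are empirical 2.5/97.5 percentiles of the
    across-locus means.
    """

    sample_id: str
    n_star: int
    B: int
    Hec: float
    Hoc: float
    Nac: float
    ci: dict[str, tuple[float, float]]
    per_locus: dict[str, dict[str, float]] = field(default_factory=dict)


def sample_diversity(table: GenotypeTable, haplotypes: HaplotypeTable | None = None) -> DiversityStats:
    """Standard (uncorrected) diversity summary for one sample."""
    He: dict[str, float] = {}
    Ho: dict[str, float] = {}
    A: dict[str, int] = {}
    n: dict[str, int] = {}
    for locus in table.loci:
        counts = table.allele_counts(locus)
        if not counts:
            warnings.warn(f"locus {locus} has no usable calls in {table.sample_id}; skipped")
            continue
        He[locus] = expected_het_unbiased(counts) if sum(counts.values()) >= 2 else 0.0
        Ho[locus] = observed_het(table, locus)
        A[locus] = len(counts)
        n[locus] = sum(counts.values()) // 2
    try:
        _, fis = fis_within(table)
    except ValueError:
        fis = None
    h = nh = None
    if haplotypes is not None:
        counts_h = haplotypes.counts()
        if counts_h:
            nh = len(counts_h)
            h = unbiased_gene_diversity(counts_h) if sum(counts_h.values()) >= 2 else None
    return DiversityStats(
        sample_id=table.sample_id,
        He=He, Ho=Ho, A=A, n=n,
        He_mean=float(np.mean(list(He.values()))) if He else float("nan"),
        Ho_mean=float(np.mean(list(Ho.values()))) if Ho else float("nan"),
        A_mean=float(np.mean(list(A.values()))) if A else float("nan"),
        fis=fis, h=h, n_haplotypes=nh,
    )


def resample_corrected(
    table: GenotypeTable,
    n_star: int,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CorrectedDiversity:
    """Sample-size-corrected diversity via B subsamples of n_star individuals.

    Subsamples are drawn without replacement. Per-locus statistics within a
    subsample use the individuals non-missing at that locus; the across-
    locus mean is recorded per subsample, and empirical percentile CIs are
    taken over those means.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if table.n_individuals < n_star:
        raise ValueError(
            f"sample {table.sample_id!r} has n={table.n_individuals} < n_star={n_star}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    genos = {locus: table.genotype_matrix(locus) for locus in table.loci}
    hec = np.empty(B)
    hoc = np.empty(B)
    nac = np.empty(B)
    per_locus_acc: dict[str, dict[str, list[float]]] = {
        locus: {"He": [], "Ho": [], "Na": []} for locus in table.loci
    }
    for b in range(B):
        idx = rng.choice(table.n_individuals, size=n_star, replace=False)
        he_l, ho_l, na_l = [], [], []
        for locus in table.loci:
            g = genos[locus][idx]
            g = g[g[:, 0] != 0]
            if g.shape[0] == 0:
                continue
            copies = np.concatenate([g[:, 0], g[:, 1]])
            _, counts = np.unique(copies, return_counts=True)
            he_l.append(expected_het_unbiased(counts) if copies.size >= 2 else 0.0)
            ho_l.append(float((g[:, 0] != g[:, 1]).mean()))
            na_l.append(float(counts.size))
            acc = per_locus_acc[locus]
            acc["He"].append(he_l[-1])
            acc["Ho"].append(ho_l[-1])
            acc["Na"].append(na_l[-1])
        hec[b] = np.mean(he_l)
        hoc[b] = np.mean(ho_l)
        nac[b] = np.mean(na_l)

    def ci(v: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    per_locus = {
        locus: {stat: float(np.mean(vals)) for stat, vals in acc.items() if vals}
        for locus, acc in per_locus_acc.items()
    }
    return CorrectedDiversity(
        sample_id=table.sample_id,
        n_star=n_star,
        B=B,
        Hec=float(hec.mean()),
        Hoc=float(hoc.mean()),
        Nac=float(nac.mean()),
        ci={"Hec": ci(hec), "Hoc": ci(hoc), "Nac": ci(nac)},
        per_locus=per_locus,
    )


def haplotype_inventory(
    tables: HaplotypeTable | Iterable[HaplotypeTable],
) -> tuple[int, dict[str, int]]:
    """Distinct haplotype count over all tables plus per-sample counts.

    Only haplotypes with nonzero occurrence count toward the inventory.
    """
    if isinstance(tables, HaplotypeTable):
        tables = [tables]
    tables = list(tables)
    distinct: set[str] = set()
    per_sample: dict[str, int] = {}
    any_entry = False
    for t in tables:
        counts = t.counts()
        if counts:
            any_entry = True
        distinct.update(counts)
        per_sample[t.sample_id] = len(counts)
    if not any_entry:
        raise ValueError("no non-missing haplotype entries")
    return len(distinct), per_sample
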