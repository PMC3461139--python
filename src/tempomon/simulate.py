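"""Forward Wright-Fisher simulator with hatchery supplementation.

The simulator emulates the study design behind a supplemented riverine
fish population: a dioecious (1:1 sex ratio) population of census size Nc
reproducing in discrete generations, with unlinked multi-allelic
microsatellite loci, a maternally inherited haploid mtDNA locus, and an
optional hatchery pathway in which a fraction phi of each new generation
is produced by captive lots bred from small broodstocks (paired or
communal matings).

The census size is decoupled from the effective size through family-size
overdispersion: parents of each sex receive gamma-distributed breeding
weights, making offspring counts Dirichlet-multinomial ("sweepstakes"
reproduction, the type III survivorship regime). The gamma shape is solved
so the expected variance effective size of each transition matches the
requested true Ne; realized per-generation Ne is also recorded from the
realized gametic contributions via the standard variance-Ne bookkeeping
Ne_s = (N_s k~ - 1)/(k~ - 1 + Vk/k~) per sex, combined as
1/Ne = 1/(4 Ne_m) + 1/(4 Ne_f).

Plan I temporal sampling draws S distinct adults before reproduction; the
sampled fish remain available as parents (sampling does not remove them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .popdata import BroodstockRecord, GenotypeTable, HaplotypeTable, SampleMeta

__all__ = ["SimConfig", "SimulationTruth", "SimulatedSample", "simulate", "scenario_presets"]


@dataclass
class SimConfig:
    """Scenario definition for the supplementation simulator.

    ``Nc`` is the census per generation (scalar or one value per
    generation, length n_generations + 1); ``true_Ne`` the target variance
    effective size of the wild reproductive pathway per transition (None =
    ideal, near-census). ``supplementation`` maps generation index (of the
    offspring generation) to the fraction phi of offspring produced by
    captive lots; ``broodstock`` describes the lots available each
    supplemented generation. ``sampling`` maps generation index to the
    Plan I sample size S drawn before reproduction.
    """

    n_generations: int
    Nc: int | list[int]
    true_Ne: float | list[float] | None = None
    L: int = 9
    k_alleles: int = 8
    n_haplotypes: int = 15
    init_alpha: float = 1.0
    supplementation: dict[int, float] = field(default_factory=dict)
    broodstock: list[BroodstockRecord] = field(default_factory=list)
    lot_size: int = 50
    n_lots: int = 1
    sampling: dict[int, int] = field(default_factory=dict)
    seed: int = 0
    name: str = "custom"

    def census(self, gen: int) -> int:
        if isinstance(self.Nc, (list, tuple, np.ndarray)):
            return int(self.Nc[min(gen, len(self.Nc) - 1)])
        return int(self.Nc)

    def target_ne(self, gen: int) -> float | None:
        if self.true_Ne is None:
            return None
        if isinstance(self.true_Ne, (list, tuple, np.ndarray)):
            return float(self.true_Ne[min(gen, len(self.true_Ne) - 1)])
        return float(self.true_Ne)

    def phi(self, gen: int) -> float:
        return float(self.supplementation.get(gen, 0.0))

    def validate(self) -> None:
        for g in range(self.n_generations + 1):
            nc = self.census(g)
            tgt = self.target_ne(g)
            if tgt is not None and tgt > nc:
                raise ValueError(f"generation {g}: true_Ne={tgt} exceeds Nc={nc}")
            if not 0.0 <= self.phi(g) <= 1.0:
                raise ValueError(f"generation {g}: phi outside [0, 1]")
            if g in self.sampling and self.sampling[g] > nc:
                raise ValueError(f"generation {g}: sample size exceeds census")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["supplementation"] = {int(k): float(v) for k, v in self.supplementation.items()}
        d["sampling"] = {int(k): int(v) for k, v in self.sampling.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["supplementation"] = {int(k): float(v) for k, v in d.get("supplementation", {}).items()}
        d["sampling"] = {int(k): int(v) for k, v in d.get("sampling", {}).items()}
        d["broodstock"] = [
            b if isinstance(b, BroodstockRecord) else BroodstockRecord(**b)
            for b in d.get("broodstock", [])
        ]
        return cls(**d)


@dataclass
class GenerationTruth:
    generation: int
    Nc: int
    phi: float
    realized_Ne: float
    target_Ne: float | None
    allele_freqs: list[np.ndarray]
    haplotype_freqs: np.ndarray
    broodstock: list[BroodstockRecord] = field(default_factory=list)


@dataclass
class SimulationTruth:
    config: SimConfig
    generations: list[GenerationTruth] = field(default_factory=list)


@dataclass
class SimulatedSample:
    generation: int
    genotypes: GenotypeTable
    haplotypes: HaplotypeTable
    meta: SampleMeta


# ---------------------------------------------------------------------------
# Family-size dispersion solver


def _dirmult_var(n_draws: int, n_parents: int, alpha: float) -> float:
    """Variance of one parent's offspring count under gamma breeding weights."""
    p = 1.0 / n_parents
    A = n_parents * alpha
    return n_draws * p * (1 - p) * (n_draws + A) / (1 + A)


def _ne_for_alpha(alpha: float, n_f: int, n_m: int, n_off: int) -> float:
    """Expected variance Ne of one transition given the gamma shape alpha."""

    def per_sex(ns: int) -> float:
        kbar = n_off / ns
        vk = _dirmult_var(n_off, ns, alpha)
        denom = kbar - 1.0 + vk / kbar
        if denom <= 0:
            return float("inf")
        return (ns * kbar - 1.0) / denom

    ne_f = per_sex(n_f)
    ne_m = per_sex(n_m)
    return 1.0 / (1.0 / (4.0 * ne_f) + 1.0 / (4.0 * ne_m))


def _solve_alpha(target_ne: float, n_f: int, n_m: int, n_off: int) -> float | None:
    """Gamma shape hitting the target Ne; None means ideal (equal weights)."""
    hi = _ne_for_alpha(1e8, n_f, n_m, n_off)
    if target_ne >= hi:
        return None  # target at or above the ideal-population ceiling
    lo = _ne_for_alpha(1e-4, n_f, n_m, n_off)
    if target_ne <= lo:
        raise ValueError(
            f"true_Ne={target_ne} unattainably small for Nc={n_f + n_m} (floor ~{lo:.1f})"
        )
    log_alpha = brentq(
        lambda la: _ne_for_alpha(10.0**la, n_f, n_m, n_off) - target_ne, -4.0, 8.0
    )
    return float(10.0**log_alpha)


def _realized_ne(k_f: np.ndarray, k_m: np.ndarray) -> float:
    """Variance Ne from realized per-parent offspring (gamete) counts."""

    def per_sex(k: np.ndarray) -> float:
        ns = k.size
        kbar = k.mean()
        vk = k.var()
        denom = kbar - 1.0 + vk / kbar
        if denom <= 0:
            return float("inf")
        return (ns * kbar - 1.0) / denom

    ne_f, ne_m = per_sex(k_f), per_sex(k_m)
    return 1.0 / (1.0 / (4.0 * ne_f) + 1.0 / (4.0 * ne_m))


# ---------------------------------------------------------------------------
# Core simulation


class _Population:
    """Arrays for one generation: genotypes (N, L, 2), mtDNA, sex."""

    def __init__(self, geno: np.ndarray, mtdna: np.ndarray, is_female: np.ndarray):
        self.geno = geno
        self.mtdna = mtdna
        self.is_female = is_female

    @property
    def n(self) -> int:
        return self.geno.shape[0]

    def allele_freqs(self) -> list[np.ndarray]:
        out = []
        for l in range(self.geno.shape[1]):
            copies = self.geno[:, l, :].ravel()
            out.append(np.bincount(copies)[1:] / copies.size)
        return out

    def haplotype_freqs(self, n_haps: int) -> np.ndarray:
        return np.bincount(self.mtdna, minlength=n_haps) / self.mtdna.size


def _init_population(cfg: SimConfig, rng: np.random.Generator) -> _Population:
    n = cfg.census(0)
    geno = np.empty((n, cfg.L, 2), dtype=np.int64)
    for l in range(cfg.L):
        freqs = rng.dirichlet(np.full(cfg.k_alleles, cfg.init_alpha))
        geno[:, l, :] = rng.choice(cfg.k_alleles, size=(n, 2), p=freqs) + 1
    hap_freqs = rng.dirichlet(np.full(cfg.n_haplotypes, cfg.init_alpha))
    mtdna = rng.choice(cfg.n_haplotypes, size=n, p=hap_freqs)
    is_female = np.zeros(n, dtype=bool)
    is_female[rng.permutation(n)[: n // 2]] = True
    return _Population(geno, mtdna, is_female)


def _mate(
    pop: _Population,
    mothers: np.ndarray,
    fathers: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Offspring genotypes and mtDNA from chosen parent indices."""
    n_off = mothers.size
    L = pop.geno.shape[1]
    pick_m = rng.integers(0, 2, size=(n_off, L))
    pick_f = rng.integers(0, 2, size=(n_off, L))
    cols = np.arange(L)[None, :]
    gam_m = pop.geno[mothers[:, None], cols, pick_m]
    gam_f = pop.geno[fathers[:, None], cols, pick_f]
    geno = np.stack([gam_m, gam_f], axis=2)
    mtdna = pop.mtdna[mothers]
    return geno, mtdna


def _weighted_parents(
    candidates: np.ndarray, n_off: int, alpha: float | None, rng: np.random.Generator
) -> np.ndarray:
    if alpha is None:
        return rng.choice(candidates, size=n_off, replace=True)
    w = rng.gamma(alpha, size=candidates.size)
    w /= w.sum()
    return rng.choice(candidates, size=n_off, replace=True, p=w)


def _captive_offspring(
    pop: _Population,
    lots: list[BroodstockRecord],
    n_supp: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Offspring produced by captive lots bred from the current population.

    Broodstock for each lot are drawn without replacement from the wild
    adults; paired lots split the lot's offspring equally among pairs
    (each pair = one male x one female), communal lots draw parents
    at random among the lot's breeders. Returns (geno, mtdna, mothers,
    fathers) with parent indices into the wild population.
    """
    females = np.where(pop.is_female)[0]
    males = np.where(~pop.is_female)[0]
    per_lot = np.full(len(lots), n_supp // len(lots), dtype=int)
    per_lot[: n_supp % len(lots)] += 1
    all_m: list[np.ndarray] = []
    all_f: list[np.ndarray] = []
    for lot, n_lot in zip(lots, per_lot):
        if n_lot == 0:
            continue
        fem = rng.choice(females, size=lot.Nf, replace=False)
        mal = rng.choice(males, size=lot.Nm, replace=False)
        if lot.mating_design == "paired":
            n_pairs = min(lot.Nf, lot.Nm)
            pair_of_off = rng.integers(0, n_pairs, size=n_lot)
            all_m.append(fem[pair_of_off])
            all_f.append(mal[pair_of_off])
        else:
            all_m.append(rng.choice(fem, size=n_lot, replace=True))
            all_f.append(rng.choice(mal, size=n_lot, replace=True))
    mothers = np.concatenate(all_m) if all_m else np.empty(0, dtype=np.int64)
    fathers = np.concatenate(all_f) if all_f else np.empty(0, dtype=np.int64)
    geno, mtdna = _mate(pop, mothers, fathers, rng)
    return geno, mtdna, mothers, fathers


def _sample_tables(
    pop: _Population, gen: int, S: int, rng: np.random.Generator, scenario: str
) -> SimulatedSample:
    idx = rng.choice(pop.n, size=S, replace=False)
    sample_id = f"{scenario}_g{gen}"
    inds = [f"{sample_id}_i{j:05d}" for j in range(S)]
    calls = [
        [(int(pop.geno[i, l, 0]), int(pop.geno[i, l, 1])) for l in range(pop.geno.shape[1])]
        for i in idx
    ]
    loci = [f"L{l + 1}" for l in range(pop.geno.shape[1])]
    geno_table = GenotypeTable(inds, loci, calls, sample_id=sample_id)
    haps = [chr(ord("A") + int(h)) for h in pop.mtdna[idx]]
    hap_table = HaplotypeTable(list(inds), haps, sample_id=sample_id)
    meta = SampleMeta(sample_id=sample_id, year=2000 + gen, reach="NA", origin="wild")
    return SimulatedSample(gen, geno_table, hap_table, meta)


def simulate(cfg: SimConfig) -> tuple[list[SimulatedSample], SimulationTruth]:
    """Run the scenario; returns Plan I samples and the per-generation truth.

    Identical config and seed give identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pop = _init_population(cfg, rng)
    samples: list[SimulatedSample] = []
    truth = SimulationTruth(config=cfg)

    for gen in range(cfg.n_generations + 1):
        if gen in cfg.sampling:
            samples.append(_sample_tables(pop, gen, cfg.sampling[gen], rng, cfg.name))
        if gen == cfg.n_generations:
            realized = float("nan")
            truth.generations.append(
                GenerationTruth(
                    generation=gen, Nc=pop.n, phi=cfg.phi(gen), realized_Ne=realized,
                    target_Ne=cfg.target_ne(gen),
                    allele_freqs=pop.allele_freqs(),
                    haplotype_freqs=pop.haplotype_freqs(cfg.n_haplotypes),
                )
            )
            break

        n_next = cfg.census(gen + 1)
        phi = cfg.phi(gen + 1)
        n_supp = int(round(phi * n_next))
        n_wild = n_next - n_supp

        females = np.where(pop.is_female)[0]
        males = np.where(~pop.is_female)[0]
        target = cfg.target_ne(gen)
        alpha = (
            None if target is None
            else _solve_alpha(target, females.size, males.size, n_wild if n_wild else n_next)
        )
        mothers = _weighted_parents(females, n_wild, alpha, rng)
        fathers = _weighted_parents(males, n_wild, alpha, rng)
        geno_w, mt_w = _mate(pop, mothers, fathers, rng)

        lots_used: list[BroodstockRecord] = []
        if n_supp > 0:
            if not cfg.broodstock:
                raise ValueError("supplementation scheduled but no broodstock configured")
            lots_used = list(cfg.broodstock)
            geno_c, mt_c, moth_c, fath_c = _captive_offspring(pop, lots_used, n_supp, rng)
            geno = np.concatenate([geno_w, geno_c])
            mtdna = np.concatenate([mt_w, mt_c])
            mothers_all = np.concatenate([mothers, moth_c])
            fathers_all = np.concatenate([fathers, fath_c])
        else:
            geno, mtdna = geno_w, mt_w
            mothers_all, fathers_all = mothers, fathers

        k_f = np.bincount(mothers_all, minlength=pop.n)[females].astype(float)
        k_m = np.bincount(fathers_all, minlength=pop.n)[males].astype(float)
        truth.generations.append(
            GenerationTruth(
                generation=gen, Nc=pop.n, phi=cfg.phi(gen),
                realized_Ne=_realized_ne(k_f, k_m),
                target_Ne=target,
                allele_freqs=pop.allele_freqs(),
                haplotype_freqs=pop.haplotype_freqs(cfg.n_haplotypes),
                broodstock=lots_used,
            )
        )

        is_female = np.zeros(n_next, dtype=bool)
        is_female[rng.permutation(n_next)[: n_next // 2]] = True
        pop = _Population(geno, mtdna, is_female)

    return samples, truth


# ---------------------------------------------------------------------------
# Scenario presets


def scenario_presets(name: str, seed: int = 0) -> SimConfig:
    """Named study-like scenarios.

    ``isolated_wf``: closed population, Nc=1000, true Ne=100, no
    supplementation; Plan I samples of 50 at generations 0 and 2 (the
    temporal-estimator recovery setting).

    ``wild_decline``: census crash 100_000 -> 1_000 over 8 generations with
    sweepstakes reproduction (Ne about Nc/10), no supplementation.

    ``supplemented_sink``: declining wild population (Ne about Nc/10)
    increasingly supplemented (phi up to 0.8) by captive lots of ~50 fish
    bred from 10-20 paired matings, the regime in which inbreeding
    (LD-based) effective size stays high while variance effective size
    collapses.
    """
    if name == "isolated_wf":
        # benchmark preset: moderately even allele spectrum (Dirichlet 5),
        # so recovery measures estimator correctness, not rare-allele bias
        return SimConfig(
            n_generations=2, Nc=1000, true_Ne=100.0, L=9, k_alleles=8,
            init_alpha=5.0, sampling={0: 50, 2: 50}, seed=seed, name=name,
        )
    if name == "wild_decline":
        census = [int(round(c)) for c in np.geomspace(100_000, 1_000, 9)]
        return SimConfig(
            n_generations=8, Nc=census,
            true_Ne=[c / 10 for c in census],
            sampling={g: 100 for g in range(9)}, seed=seed, name=name,
        )
    if name == "supplemented_sink":
        # steep wild decline with hatchery input ramping up as the wild
        # population collapses: the single-sample LD estimate lags the
        # decline (it reflects the parental generation, and residual LD
        # erodes only by (1-c)^2 per generation) while the temporal
        # estimate tracks the current, already-collapsed effective size
        census = [20000, 10000, 5000, 2500, 1250, 600, 300, 300, 300]
        phi = {7: 0.3, 8: 0.5}
        lots = [
            BroodstockRecord(lot_id=f"lot{i}", Nm=12, Nf=12, mating_design="paired")
            for i in range(4)
        ]
        return SimConfig(
            n_generations=8, Nc=census, true_Ne=[c / 10 for c in census],
            supplementation=phi, broodstock=lots, lot_size=50,
            sampling={g: 150 for g in range(4, 9)}, seed=seed, name=name,
        )
    raise ValueError(
        f"unknown preset {name!r}; available: isolated_wf, wild_decline, supplemented_sink"
    )
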