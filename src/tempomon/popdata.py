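"""Data model and file I/O for multilocus genotype and haplotype samples.

The in-memory containers mirror the inputs of a long-term genetic monitoring
program for a river fish population: diploid microsatellite genotypes
(exchanged as Genepop files), haploid mtDNA haplotype assignments, per-sample
metadata (year, river reach, wild/hatchery origin), hatchery broodstock
censuses, and environmental series (fall catch-per-unit-effort and daily
spring discharge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "HaplotypeTable",
    "SampleMeta",
    "BroodstockRecord",
    "EnvSeries",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_haplotypes_csv",
    "read_metadata_csv",
    "read_broodstock_csv",
    "frequencies_from_table",
    "counts_from_published_frequencies",
]

MISSING = (0, 0)


class GenepopParseError(ValueError):
    """Raised when a Genepop file does not conform to the dialect."""


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for one population sample.

    ``calls[i][l]`` is an unordered pair of positive-integer allele labels
    (microsatellite repeat-size codes) for individual ``i`` at locus ``l``,
    or ``(0, 0)`` for missing. A half-missing call is stored as fully
    missing: a single scored allele cannot be used without assuming the
    second, so the locus is dropped for that individual.
    """

    individuals: list[str]
    loci: list[str]
    calls: list[list[tuple[int, int]]]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual identifiers")
        for row in self.calls:
            if len(row) != len(self.loci):
                raise ValueError("call row length does not match locus count")
            for a, b in row:
                if (a == 0) != (b == 0):
                    raise ValueError(
                        "half-missing call; encode missing data as (0, 0)"
                    )
                if a < 0 or b < 0:
                    raise ValueError("allele labels must be positive integers")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def allele_counts(self, locus: str) -> dict[int, int]:
        """Gene-copy counts of each allele at ``locus`` (missing excluded)."""
        j = self.locus_index(locus)
        counts: dict[int, int] = {}
        for row in self.calls:
            a, b = row[j]
            if a == 0:
                continue
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        return counts

    def genotype_matrix(self, locus: str) -> np.ndarray:
        """(n, 2) integer array of allele labels; missing rows are (0, 0)."""
        j = self.locus_index(locus)
        return np.array([row[j] for row in self.calls], dtype=np.int64)

    def subset(self, indices: Sequence[int], sample_id: str | None = None) -> "GenotypeTable":
        return GenotypeTable(
            individuals=[f"{self.individuals[i]}#{k}" if list(indices).count(i) > 1 else self.individuals[i]
                         for k, i in enumerate(indices)],
            loci=list(self.loci),
            calls=[list(self.calls[i]) for i in indices],
            sample_id=self.sample_id if sample_id is None else sample_id,
        )


@dataclass
class HaplotypeTable:
    """Haploid (maternal) haplotype label per individual; None = missing."""

    individuals: list[str]
    haplotype: list[str | None]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.individuals) != len(self.haplotype):
            raise ValueError("individuals and haplotype lists differ in length")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.haplotype:
            if h is None:
                continue
            out[h] = out.get(h, 0) + 1
        return out


VALID_REACHES = {"Angostura", "Isleta", "SanAcacia", "NA"}
VALID_ORIGINS = {"wild", "wild_caught_egg", "captive_spawned"}


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one population sample."""

    sample_id: str
    year: int
    reach: str = "NA"
    origin: str = "wild"

    def __post_init__(self) -> None:
        if self.reach not in VALID_REACHES:
            raise ValueError(f"unknown reach {self.reach!r}; expected one of {sorted(VALID_REACHES)}")
        if self.origin not in VALID_ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}; expected one of {sorted(VALID_ORIGINS)}")


@dataclass(frozen=True)
class BroodstockRecord:
    """Breeder census of one hatchery lot (Nm males, Nf females)."""

    lot_id: str
    Nm: int
    Nf: int
    mating_design: str = "paired"

    def __post_init__(self) -> None:
        if self.Nm < 0 or self.Nf < 0:
            raise ValueError("breeder counts must be nonnegative")
        if self.Nm + self.Nf < 2:
            raise ValueError("a usable lot needs at least two breeders")
        if self.mating_design not in {"paired", "communal"}:
            raise ValueError("mating_design must be 'paired' or 'communal'")


@dataclass
class EnvSeries:
    """Environmental record for one year.

    ``cpue`` is the mean October catch per unit effort (fish / 100 m^2);
    ``daily_discharge`` holds 61 daily mean discharges (cfs) covering
    May 1 - June 30, used for the categorical spring-runoff score.
    """

    year: int
    cpue: float | None = None
    daily_discharge: np.ndarray | None = None
    runoff_score: int | None = None

    def __post_init__(self) -> None:
        if self.cpue is not None and self.cpue < 0:
            raise ValueError("cpue must be nonnegative")
        if self.daily_discharge is not None:
            self.daily_discharge = np.asarray(self.daily_discharge, dtype=float)
            if self.daily_discharge.size != 61:
                raise ValueError("daily_discharge must cover 61 days (May 1 - June 30)")
        if self.runoff_score is not None and self.runoff_score not in (10, 15, 20):
            raise ValueError("runoff_score must be one of 10, 15, 20")


# ---------------------------------------------------------------------------
# Genepop I/O


def _parse_call(token: str, allele_digits: int, lineno: int) -> tuple[int, int]:
    if len(token) != 2 * allele_digits or not token.isdigit():
        raise GenepopParseError(
            f"line {lineno}: genotype token {token!r} is not {2 * allele_digits} digits"
        )
    a = int(token[:allele_digits])
    b = int(token[allele_digits:])
    if a == 0 or b == 0:
        return MISSING
    return (a, b)


def read_genepop(path: str | Path, allele_digits: int = 3) -> list[GenotypeTable]:
    """Read a Genepop file into one :class:`GenotypeTable` per POP block.

    Zero codes ("00"/"000") denote missing alleles; a half-missing diploid
    call becomes fully missing. Population ``sample_id`` is taken from the
    last individual label of the block, per Genepop convention.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("line 1: empty file")
    # line 1 = title, then locus names (one per line or comma-separated)
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci and i < len(lines):
        raise GenepopParseError(f"line {i + 1}: no locus names before first POP")

    tables: list[GenotypeTable] = []
    inds: list[str] = []
    calls: list[list[tuple[int, int]]] = []

    def flush(lineno: int) -> None:
        if inds or tables is not None:
            if inds:
                sample_id = inds[-1]
                tables.append(
                    GenotypeTable(list(inds), list(loci), [list(c) for c in calls], sample_id)
                )
            inds.clear()
            calls.clear()

    seen_pop = False
    for lineno0, line in enumerate(lines[i:], start=i):
        lineno = lineno0 + 1
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            if seen_pop:
                flush(lineno)
            seen_pop = True
            continue
        if not seen_pop:
            raise GenepopParseError(f"line {lineno}: genotype data before first POP")
        if "," not in stripped:
            raise GenepopParseError(f"line {lineno}: missing ',' separator after individual label")
        label, geno = stripped.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {lineno}: {len(tokens)} genotypes but {len(loci)} loci declared"
            )
        inds.append(label.strip())
        calls.append([_parse_call(t, allele_digits, lineno) for t in tokens])
    if seen_pop:
        flush(len(lines))
    return tables


def write_genepop(
    tables: Iterable[GenotypeTable],
    path: str | Path,
    allele_digits: int = 3,
    title: str = "tempomon export",
) -> None:
    """Write tables as one Genepop file (one POP block per table)."""
    tables = list(tables)
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    limit = 10**allele_digits - 1
    loci = tables[0].loci if tables else []
    for t in tables:
        if t.loci != loci:
            raise ValueError("all tables must share the same locus list")
        for row in t.calls:
            for a, b in row:
                if a > limit or b > limit:
                    raise ValueError(
                        f"allele label {max(a, b)} does not fit in {allele_digits} digits"
                    )
    out = [title]
    out.extend(loci)
    for t in tables:
        out.append("pop")
        for ind, row in zip(t.individuals, t.calls):
            geno = " ".join(
                f"{a:0{allele_digits}d}{b:0{allele_digits}d}" for a, b in row
            )
            out.append(f"{ind}, {geno}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV readers for the auxiliary inputs


def read_haplotypes_csv(path: str | Path, sample_id: str = "") -> HaplotypeTable:
    """Read a 2-column CSV (individual, haplotype); blank haplotype = missing."""
    df = pd.read_csv(path, dtype=str).fillna("")
    inds = df.iloc[:, 0].tolist()
    haps = [h if h else None for h in df.iloc[:, 1].tolist()]
    return HaplotypeTable(inds, haps, sample_id=sample_id)


def read_metadata_csv(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype={"sample_id": str, "year": int, "reach": str, "origin": str})
    return [
        SampleMeta(r.sample_id, int(r.year), r.reach, r.origin)
        for r in df.itertuples(index=False)
    ]


def read_env_csv(
    path: str | Path, discharge_path: str | Path | None = None
) -> list[EnvSeries]:
    """Read yearly environment (year, cpue) plus optional daily discharge.

    The discharge file is long-format (date, cfs); for each year the 61
    days from May 1 to June 30 are extracted, and years with an incomplete
    window get no discharge vector.
    """
    df = pd.read_csv(path)
    discharge_by_year: dict[int, np.ndarray] = {}
    if discharge_path is not None:
        dd = pd.read_csv(discharge_path, parse_dates=["date"])
        for year, sub in dd.groupby(dd["date"].dt.year):
            window = sub[
                ((sub["date"].dt.month == 5))
                | ((sub["date"].dt.month == 6) & (sub["date"].dt.day <= 30))
            ].sort_values("date")
            if len(window) == 61:
                discharge_by_year[int(year)] = window["cfs"].to_numpy(dtype=float)
    return [
        EnvSeries(
            year=int(r.year),
            cpue=float(r.cpue),
            daily_discharge=discharge_by_year.get(int(r.year)),
        )
        for r in df.itertuples(index=False)
    ]


def read_broodstock_csv(path: str | Path) -> list[BroodstockRecord]:
    df = pd.read_csv(path, dtype={"lot_id": str, "Nm": int, "Nf": int, "design": str})
    return [
        BroodstockRecord(r.lot_id, int(r.Nm), int(r.Nf), r.design)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Count/frequency plumbing


def frequencies_from_table(counts: Sequence[int] | dict) -> tuple[np.ndarray, int]:
    """Relative frequencies and the total gene-copy count from raw counts.

    ``n`` is the number of gene copies observed: individuals for haploid
    data, 2x individuals for diploid allele counts (the caller supplies
    gene-copy counts either way).
    """
    if isinstance(counts, dict):
        counts = list(counts.values())
    arr = np.asarray(counts, dtype=np.int64)
    if arr.size == 0 or (arr < 0).any():
        raise ValueError("counts must be nonnegative integers")
    n = int(arr.sum())
    if n == 0:
        raise ValueError("all counts are zero")
    return arr / n, n


def counts_from_published_frequencies(freqs: Sequence[float], n: int) -> np.ndarray:
    """Recover integer counts from rounded published frequencies.

    Published tables often report relative frequencies to 3 decimals while
    the underlying data are integer counts out of ``n`` gene copies. Counts
    are reconstructed by rounding ``freq * n`` and repairing the total with
    a largest-remainder rule (ties broken by index order). A warning is
    emitted if any cell is adjusted by more than 1 count; an adjustment of
    more than 2 counts on any cell means the frequencies and ``n`` are
    irreconcilable and raises.
    """
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise ValueError("frequencies must be in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    raw = f * n
    counts = np.floor(raw + 0.5).astype(np.int64)  # round half up, matches print rounding
    deficit = n - int(counts.sum())
    if deficit != 0:
        # distribute the deficit to the cells with the largest remainders
        remainders = raw - np.floor(raw)
        step = 1 if deficit > 0 else -1
        order = np.lexsort((np.arange(f.size), -(remainders if step > 0 else -remainders)))
        adjust = np.zeros_like(counts)
        for k in range(abs(deficit)):
            adjust[order[k % f.size]] += step
        if np.abs(adjust).max() > 2:
            raise ValueError(
                "cannot reconcile frequencies with n: a cell needs an adjustment > 2"
            )
        if np.abs(adjust).max() > 1:
            warnings.warn("count reconstruction adjusted a cell by more than 1")
        counts = counts + adjust
    if (counts < 0).any():
        raise ValueError("cannot reconcile frequencies with n (negative count)")
    return counts
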