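"""Published mtDNA-ND4 haplotype frequencies from a 12-year monitoring study.

These are the printed haplotype relative frequencies (3 decimals) and
mtDNA sample sizes for wild annual samples and hatchery stocks (reared
from wild-caught eggs, or captive-spawned) of the Rio Grande silvery
minnow monitoring program. Fifteen haplotype labels occur across all
samples. Frequencies printed as 0.000 are omitted (the haplotype was not
observed in that sample).

The rows serve as worked-example inputs: converting a row back to integer
counts (largest-remainder repair against the published N) and computing
unbiased gene diversity reproduces the published per-sample h values.
"""

from __future__ import annotations

import numpy as np

from .popdata import HaplotypeTable, counts_from_published_frequencies

__all__ = [
    "HAPLOTYPE_LABELS",
    "HAPLOTYPE_FREQUENCIES",
    "MTDNA_SAMPLE_SIZES",
    "SAMPLE_ORIGIN",
    "haplotype_counts",
    "haplotype_table",
    "all_haplotype_tables",
]

HAPLOTYPE_LABELS = ["A", "C", "D", "E", "F", "K", "I", "J", "M", "N", "P", "O", "Q", "S", "T"]

# sample_id -> {haplotype: published relative frequency}
HAPLOTYPE_FREQUENCIES: dict[str, dict[str, float]] = {
    # wild annual samples
    "1987": {"A": 0.459, "C": 0.162, "D": 0.162, "E": 0.054, "F": 0.081, "K": 0.027, "M": 0.054},
    "1999": {"A": 0.750, "D": 0.114, "E": 0.068, "F": 0.045, "K": 0.023},
    "2000": {"A": 0.790, "C": 0.008, "D": 0.048, "E": 0.048, "F": 0.097, "K": 0.008},
    "2001": {"A": 0.607, "C": 0.090, "D": 0.057, "E": 0.033, "F": 0.098, "K": 0.074,
             "I": 0.008, "J": 0.016, "M": 0.008, "O": 0.008},
    "2002": {"A": 0.556, "C": 0.199, "D": 0.137, "E": 0.010, "F": 0.059, "K": 0.034,
             "J": 0.003, "O": 0.003},
    "2003": {"A": 0.671, "C": 0.054, "D": 0.150, "E": 0.030, "F": 0.054, "K": 0.012,
             "J": 0.006, "M": 0.006, "O": 0.018},
    "2004": {"A": 0.596, "C": 0.087, "D": 0.106, "E": 0.019, "F": 0.075, "K": 0.050,
             "I": 0.012, "M": 0.019, "P": 0.006, "O": 0.031},
    "2005": {"A": 0.598, "C": 0.126, "D": 0.088, "E": 0.028, "F": 0.086, "K": 0.018,
             "I": 0.015, "J": 0.003, "M": 0.028, "O": 0.010},
    "2006": {"A": 0.587, "C": 0.135, "D": 0.093, "E": 0.048, "F": 0.048, "K": 0.048,
             "I": 0.003, "M": 0.029, "O": 0.008, "T": 0.003},
    "2007": {"A": 0.628, "C": 0.110, "D": 0.083, "E": 0.023, "F": 0.087, "K": 0.037,
             "I": 0.005, "M": 0.005, "O": 0.018, "Q": 0.005},
    "2008": {"A": 0.635, "C": 0.120, "D": 0.079, "E": 0.026, "F": 0.067, "K": 0.045,
             "I": 0.004, "M": 0.009, "P": 0.002, "O": 0.006, "S": 0.006},
    "2009": {"A": 0.614, "C": 0.140, "D": 0.076, "E": 0.028, "F": 0.064, "K": 0.034,
             "I": 0.006, "J": 0.004, "M": 0.019, "P": 0.002, "O": 0.011, "S": 0.002},
    "2010": {"A": 0.562, "C": 0.124, "D": 0.097, "E": 0.032, "F": 0.069, "K": 0.053,
             "I": 0.014, "M": 0.016, "O": 0.032},
    # hatchery stocks reared from wild-caught eggs
    "WcE-01": {"A": 0.573, "C": 0.197, "D": 0.051, "E": 0.064, "F": 0.064, "K": 0.032,
               "M": 0.013, "N": 0.006},
    "WcE-SA-01": {"A": 0.569, "C": 0.137, "D": 0.059, "E": 0.059, "F": 0.098, "K": 0.078},
    "WcE-An-02": {"A": 0.653, "C": 0.020, "D": 0.327},
    "WcE-SA-02": {"A": 0.488, "C": 0.225, "D": 0.050, "E": 0.013, "F": 0.138, "K": 0.050,
                  "M": 0.038},
    "WcE-SA-03": {"A": 0.490, "C": 0.078, "D": 0.196, "E": 0.059, "F": 0.098, "K": 0.039,
                  "M": 0.020, "O": 0.020},
    "MJO07-005": {"A": 0.604, "C": 0.094, "D": 0.019, "E": 0.019, "F": 0.170, "K": 0.075,
                  "J": 0.019},
    "MJO07-006": {"A": 0.604, "C": 0.083, "D": 0.125, "E": 0.021, "F": 0.083, "K": 0.042,
                  "O": 0.042},
    # captive-spawned stocks
    "MJO06-29": {"A": 0.680, "C": 0.140, "D": 0.080, "F": 0.060, "M": 0.040},
    "Cs-01": {"A": 0.724, "C": 0.052, "E": 0.034, "F": 0.069, "K": 0.121},
    "Cs-An-02": {"D": 1.000},
    "Cs-SA-02": {"A": 0.434, "C": 0.075, "D": 0.170, "E": 0.132, "F": 0.170, "P": 0.019},
    "Cs-04": {"A": 0.596, "C": 0.255, "D": 0.021, "F": 0.043, "K": 0.064, "O": 0.021},
    "TFT039": {"A": 0.596, "C": 0.269, "D": 0.038, "K": 0.096},
    "TFT04-23": {"A": 0.617, "C": 0.043, "D": 0.191, "K": 0.043, "O": 0.106},
    "TFT04-24": {"A": 0.583, "C": 0.125, "D": 0.208, "F": 0.021, "K": 0.063},
    "TFT04-25": {"A": 0.434, "C": 0.057, "D": 0.113, "E": 0.057, "F": 0.283, "K": 0.057},
    "TFT04-29": {"A": 0.566, "C": 0.245, "E": 0.075, "K": 0.094, "M": 0.019},
    "TFT04-30": {"A": 0.400, "C": 0.333, "K": 0.244, "P": 0.022},
    "TFT04-31": {"A": 0.420, "C": 0.340, "D": 0.020, "F": 0.060, "K": 0.040, "M": 0.100,
                 "O": 0.020},
    "TFT05-06": {"A": 0.500, "C": 0.360, "D": 0.020, "F": 0.020, "K": 0.080, "M": 0.020},
    "TFT05-07": {"A": 0.625, "C": 0.292, "D": 0.021, "E": 0.063},
    "TFT05-08": {"A": 0.592, "C": 0.082, "E": 0.102, "K": 0.224},
    "TFT05-09": {"A": 0.680, "C": 0.160, "K": 0.120, "M": 0.040},
    "TFT05-11": {"A": 0.623, "C": 0.057, "D": 0.113, "E": 0.019, "F": 0.170, "M": 0.019},
    "MJO06-25": {"A": 0.551, "C": 0.245, "D": 0.061, "F": 0.061, "K": 0.082},
    "MJO06-28": {"A": 0.400, "C": 0.140, "D": 0.220, "F": 0.220, "K": 0.020},
    "MJO07-007": {"A": 0.560, "C": 0.020, "D": 0.120, "E": 0.280, "F": 0.020},
}

# published mtDNA sample sizes (sequences) per sample
MTDNA_SAMPLE_SIZES: dict[str, int] = {
    "1987": 37, "1999": 44, "2000": 124, "2001": 122, "2002": 387, "2003": 167,
    "2004": 161, "2005": 396, "2006": 378, "2007": 218, "2008": 466, "2009": 472,
    "2010": 433,
    "WcE-01": 157, "WcE-SA-01": 51, "WcE-An-02": 49, "WcE-SA-02": 80,
    "WcE-SA-03": 51, "MJO07-005": 53, "MJO07-006": 48,
    "MJO06-29": 50, "Cs-01": 58, "Cs-An-02": 51, "Cs-SA-02": 53, "Cs-04": 47,
    "TFT039": 52, "TFT04-23": 47, "TFT04-24": 48, "TFT04-25": 53, "TFT04-29": 53,
    "TFT04-30": 45, "TFT04-31": 50, "TFT05-06": 50, "TFT05-07": 48, "TFT05-08": 49,
    "TFT05-09": 50, "TFT05-11": 53, "MJO06-25": 49, "MJO06-28": 50, "MJO07-007": 50,
}

SAMPLE_ORIGIN: dict[str, str] = {
    **{s: "wild" for s in
       ["1987", "1999", "2000", "2001", "2002", "2003", "2004", "2005", "2006",
        "2007", "2008", "2009", "2010"]},
    **{s: "wild_caught_egg" for s in
       ["WcE-01", "WcE-SA-01", "WcE-An-02", "WcE-SA-02", "WcE-SA-03",
        "MJO07-005", "MJO07-006"]},
    **{s: "captive_spawned" for s in
       ["MJO06-29", "Cs-01", "Cs-An-02", "Cs-SA-02", "Cs-04", "TFT039",
        "TFT04-23", "TFT04-24", "TFT04-25", "TFT04-29", "TFT04-30", "TFT04-31",
        "TFT05-06", "TFT05-07", "TFT05-08", "TFT05-09", "TFT05-11",
        "MJO06-25", "MJO06-28", "MJO07-007"]},
}


def haplotype_counts(sample_id: str) -> dict[str, int]:
    """Integer haplotype counts for one published sample.

    Reconstructed by rounding frequency x N with largest-remainder repair
    against the published mtDNA sample size.
    """
    freqs = HAPLOTYPE_FREQUENCIES[sample_id]
    n = MTDNA_SAMPLE_SIZES[sample_id]
    labels = list(freqs)
    counts = counts_from_published_frequencies([freqs[h] for h in labels], n)
    return {h: int(c) for h, c in zip(labels, counts) if c > 0}


def haplotype_table(sample_id: str) -> HaplotypeTable:
    """Reconstructed per-individual haplotype table for one published sample."""
    counts = haplotype_counts(sample_id)
    inds: list[str] = []
    haps: list[str | None] = []
    i = 0
    for hap in HAPLOTYPE_LABELS:
        for _ in range(counts.get(hap, 0)):
            inds.append(f"{sample_id}_{i:04d}")
            haps.append(hap)
            i += 1
    return HaplotypeTable(inds, haps, sample_id=sample_id)


def all_haplotype_tables() -> list[HaplotypeTable]:
    """All published samples as reconstructed haplotype tables."""
    return [haplotype_table(s) for s in HAPLOTYPE_FREQUENCIES]
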