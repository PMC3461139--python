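import numpy as np
import pytest

from tempomon.popdata import GenotypeTable, HaplotypeTable


def random_table(rng, n=20, loci=("L1", "L2", "L3"), k=4, sample_id="s", missing=0.0):
    """A random diploid table with k equally frequent alleles per locus."""
    calls = []
    for _ in range(n):
        row = []
        for _l in loci:
            if missing and rng.random() < missing:
                row.append((0, 0))
            else:
                row.append((int(rng.integers(1, k + 1)), int(rng.integers(1, k + 1))))
        calls.append(row)
    return GenotypeTable(
        [f"{sample_id}_{i}" for i in range(n)], list(loci), calls, sample_id=sample_id
    )


def hw_table(rng, n, p, sample_id="s", locus="L1"):
    """Biallelic sample drawn exactly under Hardy-Weinberg at frequency p."""
    calls = [
        [(int(rng.random() < p) + 1, int(rng.random() < p) + 1)] for _ in range(n)
    ]
    # allele 2 with prob p under this encoding; relabel is irrelevant for tests
    return GenotypeTable([f"{sample_id}_{i}" for i in range(n)], [locus], calls, sample_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_table():
    calls = [
        [(1, 1), (1, 2)],
        [(1, 2), (2, 2)],
        [(2, 2), (1, 1)],
        [(1, 2), (0, 0)],
    ]
    return GenotypeTable(["a", "b", "c", "d"], ["L1", "L2"], calls, sample_id="toy")


@pytest.fixture
def toy_haplotypes():
    return HaplotypeTable(["a", "b", "c", "d", "e"], ["A", "A", "B", "C", None], "toyh")
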