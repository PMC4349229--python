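import itertools

import numpy as np
import pytest

from sweepscan.io import HaplotypeSet


# ---------------------------------------------------------------------------
# Brute-force oracles, deliberately independent of the implementations
# ---------------------------------------------------------------------------


def pi_bruteforce(haps: np.ndarray) -> float:
    """Mean pairwise difference by explicit pair enumeration."""
    n = haps.shape[0]
    diffs = [
        int((haps[i] != haps[j]).sum())
        for i, j in itertools.combinations(range(n), 2)
    ]
    return sum(diffs) / len(diffs)


def hudson_fst_bruteforce(pop1: np.ndarray, pop2: np.ndarray) -> float:
    """1 - pi_w/pi_t with every pi from pair enumeration."""
    n1, n2 = pop1.shape[0], pop2.shape[0]
    pi_w = (n1 * pi_bruteforce(pop1) + n2 * pi_bruteforce(pop2)) / (n1 + n2)
    pi_t = pi_bruteforce(np.vstack([pop1, pop2]))
    return 1.0 - pi_w / pi_t


def ehh_bruteforce(haps: np.ndarray, core: int, allele: int, span: slice) -> float:
    """Pair-identity probability of core-allele carriers over a site span."""
    carriers = haps[haps[:, core] == allele][:, span]
    n_c = carriers.shape[0]
    pairs = list(itertools.combinations(range(n_c), 2))
    same = sum(1 for i, j in pairs if np.array_equal(carriers[i], carriers[j]))
    return same / len(pairs)


def distinct_haplotypes_bruteforce(haps: np.ndarray) -> int:
    return len({tuple(row) for row in haps})


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------


def make_hapset(alleles, positions=None, populations=None, chrom=None):
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_sites = alleles.shape
    if positions is None:
        positions = np.arange(n_sites) * 100
    if populations is None:
        populations = np.array(["pop"] * n_hap)
    if chrom is None:
        chrom = np.full(n_sites, "1")
    return HaplotypeSet(
        alleles=alleles,
        chrom=np.asarray(chrom),
        positions=np.asarray(positions),
        populations=np.asarray(populations),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_three_pop(rng):
    """Random (non-demographic) three-population haplotypes for contract
    tests that only need shapes and labels."""
    n_sites = 400
    alleles = rng.integers(0, 2, size=(60, n_sites), dtype=np.uint8)
    # ensure segregating everywhere
    alleles[0] = 0
    alleles[1] = 1
    populations = np.array(["breed1"] * 24 + ["breed2"] * 20 + ["outgroup"] * 16)
    return make_hapset(alleles, populations=populations)
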