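import numpy as np
import pytest

from chromaforge.matrix import ContactMatrix
from chromaforge.regions import GenomicRegion, RegionSet, make_bins
from chromaforge.simulate import SimulationConfig, simulate_matrix


@pytest.fixture
def three_bin_matrix():
    """3-bin single-chromosome matrix with known diagonals (5,5,5),(2,4),(1)."""
    bins = make_bins({"chr1": 30}, 10)
    dense = np.array([[5.0, 2.0, 1.0], [2.0, 5.0, 4.0], [1.0, 4.0, 5.0]])
    return ContactMatrix.from_dense(bins, dense)


@pytest.fixture(scope="session")
def plaid_matrix():
    """Balanced 1000-bin plaid (checkerboard compartment) fixture with truth."""
    config = SimulationConfig(
        seed=11, chromosome_lengths={"chr1": 10_000_000}, bin_size=10_000,
        plaid_contrast=0.6, compartment_size=25, scale=30,
    )
    matrix, truth = simulate_matrix(config)
    matrix.balance("kr")
    return matrix, truth


@pytest.fixture(scope="session")
def tad_matrix():
    """Balanced matrix with 10 planted TAD boundaries and sigma=0.2 noise."""
    config = SimulationConfig(
        seed=12, chromosome_lengths={"chr1": 10_000_000}, bin_size=10_000,
        n_boundaries=10, tad_enrichment=3.0, noise_sigma=0.2, scale=40,
    )
    matrix, truth = simulate_matrix(config)
    matrix.balance("kr")
    return matrix, truth


@pytest.fixture(scope="session")
def loop_matrix():
    """Deeply covered matrix with 20 planted 8x loops."""
    config = SimulationConfig(
        seed=13, chromosome_lengths={"chr1": 5_000_000}, bin_size=10_000,
        n_loops=20, loop_fold=8.0, scale=500,
    )
    matrix, truth = simulate_matrix(config)
    matrix.balance("kr")
    return matrix, truth


def region(chrom, start, end, strand="."):
    return GenomicRegion(chrom, start, end, strand)
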