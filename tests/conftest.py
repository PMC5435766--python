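import numpy as np
import pytest

from hybridqg import simdata, genotype
from hybridqg.core import GeneticMap, default_map


@pytest.fixture(scope="session")
def small_map():
    return default_map(n_chromosomes=3, chrom_length_cm=60.0, markers_per_chrom=12)


@pytest.fixture(scope="session")
def dh_small(small_map):
    return simdata.simulate_dh_population(small_map, 48, seed=11)


@pytest.fixture(scope="session")
def design_small(dh_small):
    return simdata.make_crossing_design(list(dh_small.individual_ids), 80, seed=11)


@pytest.fixture(scope="session")
def hybrids_small(dh_small, design_small):
    return genotype.infer_hybrid_genotypes(dh_small, design_small)


@pytest.fixture(scope="session")
def combined_small(dh_small, hybrids_small):
    return dh_small.concat(hybrids_small)


@pytest.fixture(scope="session")
def groups_small(combined_small):
    return dict(zip(combined_small.individual_ids, combined_small.group))


@pytest.fixture(scope="session")
def two_unlinked_map():
    """Two chromosomes far enough apart that loci are effectively unlinked."""
    chrom = np.array(["A01"] * 2 + ["A02"] * 2, dtype=object)
    mid = np.array([f"m{i}" for i in range(4)], dtype=object)
    pos = np.array([0.0, 300.0, 0.0, 300.0])
    return GeneticMap(chrom, mid, pos)
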