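import numpy as np
import pytest

from snppanel.matrix import MISSING, GenotypeMatrix, PopulationSpec
from snppanel.simulate import SimConfig, simulate_reference, simulate_two_pop_genotypes


@pytest.fixture
def tiny_matrix():
    """3 samples x 4 sites with one missing call and depths."""
    sites = [("chr1", 100, "A", "G"), ("chr1", 250, "C", "T"),
             ("chr2", 50, "G", "A"), ("chr2", 900, "T", "C")]
    codes = np.array(
        [[0, 1, 2, 0],
         [1, MISSING, 2, 1],
         [2, 0, 2, 0]], dtype=np.int8)
    depths = np.array(
        [[10, 20, 5, 30],
         [8, 0, 12, 15],
         [25, 14, 9, 40]], dtype=np.int32)
    return GenotypeMatrix(["s1", "s2", "s3"], sites, codes, depths)


@pytest.fixture(scope="session")
def sim_study():
    """One seeded two-population study reused across tests."""
    cfg = SimConfig(seed=424242, n_sites=2000, F=0.3)
    genome = simulate_reference(cfg.chrom_lengths, seed=7)
    matrix, pops = simulate_two_pop_genotypes(cfg, genome=genome)
    return cfg, genome, matrix, pops


@pytest.fixture
def two_pop_spec():
    def _make(sample_ids, n1):
        return PopulationSpec(
            {s: ("A" if i < n1 else "B") for i, s in enumerate(sample_ids)}
        )
    return _make
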