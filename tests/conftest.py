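import numpy as np
import pytest

from kinscape import GenotypeTable, SimulationSpec, simulate_island_genotypes


@pytest.fixture(scope="session")
def small_table() -> GenotypeTable:
    """3 individuals x 2 loci with one missing call."""
    calls = np.array([
        [[1, 2], [3, 3]],
        [[2, 2], [1, 3]],
        [[1, 1], [-1, -1]],
    ], dtype=np.int32)
    return GenotypeTable(["a", "b", "c"], ["locA", "locB"], calls,
                         ["g1", "g1", "g2"])


@pytest.fixture(scope="session")
def empirical_like_freqs() -> dict:
    """19-locus, 10-allele frequency panel with He near 0.78."""
    rng = np.random.default_rng(0)
    freqs = {}
    for j in range(19):
        p = rng.dirichlet(np.full(10, 0.5))
        p = np.maximum(p, 1e-4)
        p /= p.sum()
        freqs[f"loc_{j:02d}"] = {a + 1: float(x) for a, x in enumerate(p)}
    return freqs


@pytest.fixture(scope="session")
def island_table():
    """Default-condition island-model table (18 demes x 15, 19 loci)."""
    spec = SimulationSpec(master_seed=42)
    table, truth = simulate_island_genotypes(spec)
    return table, truth, spec
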