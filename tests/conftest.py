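import numpy as np
import pytest
from hypothesis import settings

from paleopop import fstats, simulate
from paleopop.genotypes import AlleleCountTable, assign_blocks_equal

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240)


@pytest.fixture()
def toy_counts():
    """Hand-sized 5-group, 6-SNP count table with no missingness."""
    rng = np.random.default_rng(7)
    groups = ["A", "B", "C", "D", "E"]
    n = np.full((5, 6), 20.0)
    x = rng.integers(1, 20, size=(5, 6)).astype(float)
    blocks = assign_blocks_equal(6, 3)
    return AlleleCountTable(groups=groups, x=x, n=n,
                            blocks=blocks.block_of, n_blocks=3)


@pytest.fixture(scope="session")
def admixed_counts():
    """Simulated alpha=0.3 two-source mixture, reused across tests."""
    cfg = simulate.SimulationConfig(
        n_snps=100_000, samples_per_pop=10, n_blocks=50, seed=31,
    )
    model = simulate.admixture_model(alpha=0.3)
    freqs = simulate.simulate_frequencies(model, cfg)
    return simulate.simulate_counts(freqs, cfg)


@pytest.fixture(scope="session")
def tree_counts():
    """Counts from a 4-leaf drift tree ((A,B),(C,D)) plus its truth."""
    model = simulate.DemographyModel(
        populations=["A", "B", "C", "D"],
        edges=[("AB", "ROOT", 0.02), ("CD", "ROOT", 0.02),
               ("A", "AB", 0.03), ("B", "AB", 0.04),
               ("C", "CD", 0.05), ("D", "CD", 0.02)],
    )
    cfg = simulate.SimulationConfig(
        n_snps=100_000, samples_per_pop=10, n_blocks=50, seed=45,
    )
    counts = simulate.simulate_counts(simulate.simulate_frequencies(model, cfg), cfg)
    return counts, model


@pytest.fixture(scope="session")
def tree_f2_blocks(tree_counts):
    counts, _ = tree_counts
    return fstats.extract_f2(counts)
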