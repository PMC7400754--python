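import numpy as np
import pytest

from sigcontext.intervals import ContextAnnotation, GenomeIndex
from sigcontext.simulate import SimulationConfig, simulate_genome, synthetic_signatures


@pytest.fixture(scope="session")
def toy_genome() -> GenomeIndex:
    """Seeded 2 x 200 kb genome with every trinucleotide present."""
    cfg = SimulationConfig(seed=11, n_chroms=2, chrom_length=200_000)
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def signatures4():
    """Four well-separated sparse synthetic signatures."""
    return synthetic_signatures(4, seed=5)


@pytest.fixture(scope="session")
def late_early(toy_genome):
    """Two complementary contexts that exactly partition the toy genome."""
    late = ContextAnnotation.from_tuples(
        "late",
        [(c, 0, toy_genome.length(c) // 2) for c in toy_genome.chrom_names],
        toy_genome,
    )
    early = late.complement(toy_genome, "early")
    return late, early


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
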