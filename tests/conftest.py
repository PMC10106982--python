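import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cinpipe.simulate import generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome genome with genes on both strands, ~70 kb each."""
    g = generate_genome(n_chrom=2, length_range=(60_000, 80_000), gene_density=0.35, seed=11)
    g.validate()
    return g


@pytest.fixture(scope="session")
def fixture_genome_10kb():
    """Single 10 kb chromosome, dense gene placement on both strands."""
    g = generate_genome(n_chrom=1, length_range=(10_000, 10_000), gene_density=0.8, seed=7)
    g.validate()
    strands = {gene.strand for gene in g.genes}
    assert strands == {"+", "-"}, "fixture must carry genes on both strands"
    return g


@pytest.fixture(scope="session")
def chrom_lengths_16():
    """16 chromosomes with varied lengths, all >= 2x the telomere window."""
    rng = np.random.default_rng(123)
    return {
        f"chr{i:02d}": int(rng.integers(150_000, 400_000)) for i in range(1, 17)
    }
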