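import pandas as pd
import pytest

from roseq.synth import CohortConfig, generate_genome, generate_sample


def mkreads(rows):
    """rows of (chrom, start, end, strand[, sequence]) -> reads frame."""
    cols = ["chrom", "start", "end", "strand", "sequence"][: len(rows[0])]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_genes=30, depth_per_sample=120_000, with_sequences=True, seed=5
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config, 11)


@pytest.fixture(scope="session")
def gro_sample(small_config, small_genome):
    annos, sizes = small_genome
    return generate_sample(annos, sizes, "GRO", "CIRC", small_config, 21)


@pytest.fixture(scope="session")
def pro_sample(small_config, small_genome):
    annos, sizes = small_genome
    return generate_sample(annos, sizes, "PRO", "TSRT", small_config, 22)
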