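import numpy as np
import pytest

from rainbowseq.simulate import (
    SyntheticConfig,
    simulate_annotation_and_reads,
    simulate_cells_and_expression,
    truth_lineages,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, n_genes=300, n_transcripts=120)


@pytest.fixture(scope="session")
def expr_data(small_config):
    """(cells-with-truth-lineage, fpkm, truth) for a small seeded study."""
    cells, fpkm, truth = simulate_cells_and_expression(small_config)
    return truth_lineages(cells), fpkm, truth


@pytest.fixture(scope="session")
def annotation_data(small_config):
    return simulate_annotation_and_reads(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
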