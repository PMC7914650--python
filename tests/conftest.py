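import pytest

from butyrnet import load_table1_fixture
from butyrnet.simulate import SimulationConfig


@pytest.fixture(scope="session")
def table1():
    """The packaged table of 24 curated miRNA-mRNA interactions."""
    return load_table1_fixture()


@pytest.fixture
def small_config():
    """A small, fast simulation configuration."""
    return SimulationConfig(
        seed=11,
        n_mirna=60,
        n_mrna=300,
        frac_regulated=0.2,
        n_planted_pairs=10,
        n_decoy_predictions=60,
        interactome_size=120,
        n_gene_sets=5,
        set_size_range=(5, 20),
        n_splicing_events=200,
        n_replicates=3,
    )
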