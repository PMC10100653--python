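import pytest

from nestprime import make_benchmark_template, make_reference_db
from nestprime.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def benchmark_template():
    """657-bp template carrying perfect sites for the published primer sets."""
    return make_benchmark_template()


@pytest.fixture(scope="session")
def small_db():
    """Small 2-clade x 2-subclade synthetic reference database."""
    return make_reference_db(
        SimulationConfig(seed=7, n_clades=2, n_subclades_per_clade=2,
                         n_records_per_subclade=3, gene_length=300)
    )
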