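import pytest

from karyoevol import EventModel, sankoff_reconstruct
from karyoevol.cli import assemble_case_study_states
from karyoevol.io_formats import read_tree


@pytest.fixture(scope="session")
def case_inputs():
    """(tree, karyograms, merged tip states, default model) for the fixtures."""
    return assemble_case_study_states()


@pytest.fixture(scope="session")
def case_result(case_inputs):
    """Default-cost reconstruction on the packaged case study (shared: ~4 s)."""
    tree, _, tips, model = case_inputs
    return sankoff_reconstruct(tree, tips, model)


@pytest.fixture(scope="session")
def case_result_equal_costs(case_inputs):
    """Same reconstruction with fission cost lowered to the fusion cost."""
    tree, _, tips, _ = case_inputs
    return sankoff_reconstruct(tree, tips, EventModel(fission_cost=1.0))


@pytest.fixture
def toy_tree():
    def _make(newick):
        return read_tree(newick)

    return _make
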