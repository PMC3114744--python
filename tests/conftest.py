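import pytest

from metalign import BuiltinAligner, SimulationConfig, simulate


@pytest.fixture(scope="session")
def backend():
    return BuiltinAligner()


@pytest.fixture(scope="session")
def small_truth():
    """A small, moderately diverged simulated problem used across tests."""
    return simulate(
        SimulationConfig(
            n_leaves=5, root_length=300, total_tree_length=0.8, seed=101
        )
    )
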