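import numpy as np
import pytest

import micsim as m


@pytest.fixture
def maze():
    return m.build_double_t_maze()


@pytest.fixture
def params():
    return m.AgentParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_results():
    """Full 50-run x 100-trial results for the scenarios the qualitative
    pattern checks need, computed once per session under a fixed seed."""
    return {
        name: m.run_experiment(m.make_scenario(name), 1)
        for name in ("sim1", "sim3", "sim4", "sim5")
    }
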