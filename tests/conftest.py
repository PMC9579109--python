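import numpy as np
import pytest

import graywhale_sdp as g


@pytest.fixture(scope="session")
def area():
    return g.StudyArea.default()


@pytest.fixture(scope="session")
def season():
    return g.SeasonGrid()


@pytest.fixture(scope="session")
def truth():
    return g.ScenarioTruth()


@pytest.fixture(scope="session")
def prey(truth):
    return g.prey_field_from_truth(truth, n_categories=6)


@pytest.fixture(scope="session")
def bio():
    return g.BioenergeticParams()


@pytest.fixture(scope="session")
def small_policy(area, season, prey):
    """A coarse but real policy shared across simulation tests."""
    solver = g.PolicySolver(n_fat=24, n_fetal=12, n_lengths=3,
                            rule="class_softmax", temperature=0.001)
    solver.fit(area, season, prey, fitness="low")
    return solver.policy_


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
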