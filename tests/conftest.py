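import numpy as np
import pytest

from iccsim import ScoreMatrix, compute_anova, fixture_table5


@pytest.fixture(scope="session")
def emg_matrix():
    """Bundled 10 x 3 electromyography reliability matrix (Hz)."""
    return fixture_table5()


@pytest.fixture(scope="session")
def emg_anova(emg_matrix):
    return compute_anova(emg_matrix)


@pytest.fixture(scope="session")
def tiny_matrix():
    """2 x 2 hand-oracle matrix: SST=5, SSBS=4, SSBM=1, SSE=0."""
    return ScoreMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))


@pytest.fixture(scope="session")
def tiny_anova(tiny_matrix):
    return compute_anova(tiny_matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
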