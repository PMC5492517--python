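import numpy as np
import pytest

from drivefatigue.pipeline import run_end_to_end


@pytest.fixture(scope="session")
def e2e_report():
    """One default end-to-end pipeline run (seed 42), shared across tests.

    Session-scoped because the run (simulation + feature extraction +
    network training) takes several seconds.
    """
    return run_end_to_end({"seed": 42})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
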