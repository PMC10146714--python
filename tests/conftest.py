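import numpy as np
import pytest

from thmrisk.config import default_config
from thmrisk.pipeline import RunConfig


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_run(cfg):
    """A fast shared-stall run reused by pipeline-level tests."""
    return RunConfig(iterations=1500, seed=7, population="shared", n_events=10, config=cfg)
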