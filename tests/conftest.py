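import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wmazeseq.config import SimConfig
from wmazeseq.pipeline import prepare_behavior
from wmazeseq.synthio import simulate_session


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        seed=11, n_trials=16, n_ca1=24, n_pfc=12, swr_rate_hz=0.4, error_rate=0.2
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return simulate_session(small_cfg)


@pytest.fixture(scope="session")
def small_prepared(small_session):
    """(linearized, trials, loco_ivals, immob_ivals, dwell_ivals)."""
    return prepare_behavior(small_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
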