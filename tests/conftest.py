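import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from discaug import SimConfig, Theory, simulate_experiment


@pytest.fixture(scope="session")
def cm_dataset():
    """One Experiment-1-sized dataset generated under the causal-model pattern."""
    cfg = SimConfig(n_participants=40, seed=7, theory=Theory.CM, effect_scale=1.0)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """A small null dataset for cheap fitting tests."""
    cfg = SimConfig(n_participants=12, seed=3, theory=Theory.IM)
    return simulate_experiment(cfg)
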