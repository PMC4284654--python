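import numpy as np
import pytest
from hypothesis import settings

from wmforget import design as dsg
from wmforget import synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down design: 2 Phase-1 blocks of 8 trials, 2x4 switch trials."""
    return dsg.ExperimentDesign(p1_blocks=2, p1_trials_per_block=8, p2_blocks=2, p2_switch_per_block=4)


@pytest.fixture(scope="session")
def small_cfg():
    return synth.GroundTruthConfig(n_participants=2, n_voxels=60, n_informative=20, seed=7)


@pytest.fixture(scope="session")
def small_study(small_cfg, small_design):
    return synth.generate_dataset(small_cfg, small_design)


@pytest.fixture(scope="session")
def default_participant():
    """One participant generated under the default study conditions."""
    cfg = synth.GroundTruthConfig(n_participants=1, seed=3)
    return synth.generate_dataset(cfg).participants[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
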