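import numpy as np
import pytest
from hypothesis import settings

from seqreach.layout import make_target_layout
from seqreach.simulate import ParticipantProfile, SimConfig

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def layout():
    return make_target_layout()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def profile():
    return ParticipantProfile(
        id="P000", reward_group="Rew", drug_group="Ctrl", wm_true=0.0,
        vigour0=25.0, vigour_slope=0.01, fusion0=0.1, fusion_slope=1e-3,
        noise_sd=0.02,
    )


@pytest.fixture()
def noise_free_config():
    return SimConfig(noise_sd=0.0, peak_jitter_sd=0.0, fusion_jitter_sd=0.0,
                     reaction_jitter_sd=0.0)
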