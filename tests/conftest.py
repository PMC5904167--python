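import numpy as np
import pytest

from infoseek import synthetic_eeg as seeg
from infoseek import task_model as tm
from infoseek import task_simulator as sim


@pytest.fixture(scope="session")
def state_graph():
    return tm.enumerate_state_graph(cards_total=5, majority=3)


@pytest.fixture(scope="session")
def oracle_table():
    return tm.exhaustive_oracle(cards_total=5)


@pytest.fixture(scope="session")
def small_task():
    """One-block task used throughout the EEG tests to keep runs short."""
    return sim.TaskParams(n_blocks=1, trials_per_block=10, catch_rate=0.0)


@pytest.fixture(scope="session")
def informative_agent():
    """Agent that (almost) always buys information, so every card event
    carries true prediction-error labels."""
    return sim.AgentParams(info_value=10.0)


@pytest.fixture(scope="session")
def small_session(small_task, informative_agent):
    return sim.simulate_session(
        "sub-01", agent=informative_agent, task=small_task, seed=11
    )


@pytest.fixture(scope="session")
def no_noise():
    return seeg.NoiseParams(
        white_sd=0.0, pink_scale=0.0, participant_sd=0.0, trial_sd=0.0
    )


@pytest.fixture(scope="session")
def reduced_montage():
    return seeg.FRONTOCENTRAL + seeg.MASTOIDS


@pytest.fixture(scope="session")
def quiet_recording(small_session, no_noise, reduced_montage):
    """Noiseless forward model of a short informative session at 200 Hz."""
    return seeg.synthesize_recording(
        small_session,
        specs=seeg.default_component_specs(),
        noise=no_noise,
        montage=reduced_montage,
        sample_rate=200.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noisy_recording(small_session, reduced_montage):
    return seeg.synthesize_recording(
        small_session,
        specs=seeg.default_component_specs(),
        noise=seeg.NoiseParams(),
        montage=reduced_montage,
        sample_rate=200.0,
        seed=1,
    )
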