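import numpy as np
import pytest

from sandgait.core_io import TrialRecording
from sandgait.synthetic import (
    GaitSimConfig,
    SubstrateSpec,
    simulate_study,
    simulate_trial,
    synthetic_schema,
)


def make_trial(markers, *, rate=200.0, surface_z=0.0, direction=1, mass=70.0, emg=None, emg_rate=1110.0):
    """Minimal TrialRecording for hand-built marker dictionaries."""
    return TrialRecording(
        trial_id="T0",
        participant_id="P00",
        sex="female",
        body_mass=mass,
        height=1.75,
        substrate_id="hard_floor",
        substrate_surface_z=surface_z,
        travel_direction=direction,
        marker_rate=rate,
        markers=markers,
        emg_rate=emg_rate,
        emg=emg or {},
    )


@pytest.fixture(scope="session")
def schema():
    return synthetic_schema()


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny noise-free study configuration shared by integration tests."""
    return GaitSimConfig(
        n_participants=2,
        substrates=[
            SubstrateSpec("hard_floor", 0.0, 0.0, 0.0, 0.0, 0.0, 1.38, 0.10, 1),
            SubstrateSpec("play_sand", 0.10, 4.09, 5.23, 0.93, 1.5, 1.18, 0.10, 2),
        ],
        marker_noise_sd=0.0,
        emg_envelope_only=True,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def one_trial(small_cfg):
    rng = np.random.default_rng(7)
    return simulate_trial(small_cfg, 0, small_cfg.substrates[1], rng, 0)
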