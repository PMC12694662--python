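"""Shared fixtures: small synthetic recordings and epoch sets.

Everything is generated at test time; no stored data.  Sessions are kept
deliberately short (few trials, short idle blocks) so the full suite runs
on one CPU.
"""

import numpy as np
import pytest

from mrcpdet import (
    Epoch,
    EpochSet,
    SimulationConfig,
    generate_cohort,
    prepare_session,
)

FS = 512.0


@pytest.fixture(scope="session")
def high_snr_config() -> SimulationConfig:
    """One easy session: large MRCP, little noise."""
    return SimulationConfig(
        n_participants=1,
        sessions_per_participant=1,
        trials_per_movement=10,
        mrcp_peak_amplitude_mean=10.0,
        noise_std=1.0,
        idle_block_duration=30.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def high_snr_recording(high_snr_config):
    return generate_cohort(high_snr_config)[0]


@pytest.fixture(scope="session")
def high_snr_session(high_snr_recording):
    return prepare_session(high_snr_recording)


def make_epoch(
    data: np.ndarray,
    label: str = "movement_intention",
    epoch_id: str = "e0",
) -> Epoch:
    """Bare epoch around an array (channels x samples)."""
    return Epoch(
        epoch_id=epoch_id,
        label=label,
        data=np.asarray(data, dtype=float),
        recording_id="rec",
        anchor=0,
        window=(-2.0, 0.0),
        participant_id="P00",
        session_day=1,
        group="able_bodied",
        movement_type="wrist",
    )


def make_epoch_set(epochs, channel_labels=("C3", "C1", "Cz", "C2", "C4"), fs=FS) -> EpochSet:
    return EpochSet(epochs=list(epochs), channel_labels=tuple(channel_labels), sampling_rate=fs)
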