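"""End-to-end glue: continuous recordings -> balanced, labeled epochs.

Movement anchors come either from the stored ground-truth onsets, from
EMG onset detection, or from the cue triggers (the able-bodied
convention when no EMG was recorded).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .classify import SessionEpochs
from .emg import OnsetParams, detect_onsets
from .errors import ConfigError
from .preprocess import DEFAULT_REJECT_UV, preprocess_recording, preprocess_emg
from .simulate import ContinuousRecording

__all__ = ["prepare_session", "prepare_cohort"]

OnsetSource = Literal["true", "emg", "cue"]


def _resolve_onsets(
    recording: ContinuousRecording,
    onset_source: OnsetSource,
    onset_params: OnsetParams,
) -> np.ndarray:
    if onset_source == "true":
        if recording.true_onsets.size == 0:
            raise ConfigError(
                f"{recording.recording_id} carries no ground-truth onsets; "
                "use onset_source='emg' or 'cue'"
            )
        return recording.true_onsets
    if onset_source == "cue":
        return recording.cue_events
    if onset_source == "emg":
        emg_labels = recording.emg_channels
        if not emg_labels:
            raise ConfigError(
                f"{recording.recording_id} has no EMG channel for onset detection"
            )
        emg = preprocess_emg(recording.channel(emg_labels[0]), recording.sampling_rate)
        return detect_onsets(emg, recording.sampling_rate, onset_params)
    raise ConfigError(f"unknown onset_source {onset_source!r}")


def prepare_session(
    recording: ContinuousRecording,
    onset_source: OnsetSource = "true",
    idle_policy: str | None = None,
    reject_uv: float = DEFAULT_REJECT_UV,
    balance_seed: int = 0,
    onset_params: OnsetParams = OnsetParams(),
) -> SessionEpochs:
    """Preprocess one recording into its balanced session epochs."""
    onsets = _resolve_onsets(recording, onset_source, onset_params)
    epochs = preprocess_recording(
        recording,
        onsets=onsets,
        idle_policy=idle_policy,
        reject_uv=reject_uv,
        balance_seed=balance_seed,
    )
    return SessionEpochs(
        participant_id=recording.participant_id,
        session_day=recording.session_day,
        movement_type=recording.movement_type,
        group=recording.group,
        epochs=epochs,
    )


def prepare_cohort(
    recordings: Sequence[ContinuousRecording],
    onset_source: OnsetSource = "true",
    idle_policy: str | None = None,
    reject_uv: float = DEFAULT_REJECT_UV,
    balance_seed: int = 0,
    onset_params: OnsetParams = OnsetParams(),
) -> list[SessionEpochs]:
    """Preprocess a whole cohort of recordings (order preserved)."""
    return [
        prepare_session(
            r,
            onset_source=onset_source,
            idle_policy=idle_policy,
            reject_uv=reject_uv,
            balance_seed=balance_seed,
            onset_params=onset_params,
        )
        for r in recordings
    ]
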