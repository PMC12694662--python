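"""Filtering, epoch extraction, artifact rejection and class balancing.

EEG is band-passed 0.1-30 Hz with a 4th-order zero-phase Butterworth
(forward-backward application), EMG 20-100 Hz plus a 48-52 Hz notch and
rectification.  Movement-intention epochs cover [-2, 0) s relative to the
movement onset; idle epochs come either from dedicated idle blocks or
from the [-5, -3) s pre-cue window.  Epochs whose absolute amplitude
exceeds 150 µV on any channel are rejected, and the idle class is
subsampled to match the movement class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import signal as sps

from .errors import BalanceError, ConfigError, ShapeError
from .simulate import ContinuousRecording

__all__ = [
    "FilterSpec",
    "EEG_FILTER",
    "EMG_BANDPASS",
    "EMG_NOTCH",
    "Epoch",
    "EpochSet",
    "bandpass_filter",
    "preprocess_emg",
    "extract_epochs",
    "reject_artifacts",
    "balance_classes",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)

MOVEMENT_LABEL = "movement_intention"
IDLE_LABEL = "idle"
EPOCH_DURATION_S = 2.0
DEFAULT_REJECT_UV = 150.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description.

    ``order`` is the design order handed to the Butterworth prototype
    (a band filter of design order 4 has 4 poles per band edge).
    ``zero_phase`` selects forward-backward application, which cancels
    the phase response at the cost of doubling the effective order.
    """

    kind: Literal["bandpass", "notch"]
    low_hz: float
    high_hz: float
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "notch"):
            raise ConfigError(f"kind must be 'bandpass' or 'notch', got {self.kind!r}")
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz!r}, {self.high_hz!r})"
            )
        if self.order < 1:
            raise ConfigError(f"order must be >= 1, got {self.order!r}")

    def sos(self, sampling_rate: float) -> np.ndarray:
        if self.high_hz >= sampling_rate / 2:
            raise ConfigError(
                f"high_hz={self.high_hz} must be below the Nyquist frequency "
                f"({sampling_rate / 2} Hz)"
            )
        btype = "bandpass" if self.kind == "bandpass" else "bandstop"
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype=btype, fs=sampling_rate, output="sos"
        )


EEG_FILTER = FilterSpec("bandpass", 0.1, 30.0, order=4)
EMG_BANDPASS = FilterSpec("bandpass", 20.0, 100.0, order=4)
EMG_NOTCH = FilterSpec("notch", 48.0, 52.0, order=4)


def bandpass_filter(
    signal: np.ndarray, spec: FilterSpec, sampling_rate: float
) -> np.ndarray:
    """Apply a Butterworth filter along the last axis.

    Zero-phase specs run the cascade forward and backward
    (``sosfiltfilt`` with its reflective edge padding), which leaves the
    passband phase untouched so epoch timing is preserved.
    """
    x = np.asarray(signal, dtype=float)
    sos = spec.sos(sampling_rate)
    if x.shape[-1] <= 3 * (2 * sos.shape[0] + 1):
        raise ShapeError(
            f"signal length {x.shape[-1]} too short for a design-order "
            f"{spec.order} zero-phase filter"
        )
    if spec.zero_phase:
        # reflect-pad by ~3x the impulse-response scale of the slowest
        # corner; the scipy default is far too short for a 0.1 Hz edge
        padlen = int(min(x.shape[-1] - 1, round(3.0 * sampling_rate / spec.low_hz)))
        return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)
    return sps.sosfilt(sos, x, axis=-1)


def preprocess_emg(emg: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Condition raw EMG for onset detection: 20-100 Hz band-pass, then a
    48-52 Hz notch, then full-wave rectification."""
    if sampling_rate <= 200:
        raise ConfigError(
            f"EMG preprocessing needs sampling_rate > 200 Hz, got {sampling_rate!r}"
        )
    filtered = bandpass_filter(emg, EMG_BANDPASS, sampling_rate)
    notched = bandpass_filter(filtered, EMG_NOTCH, sampling_rate)
    return np.abs(notched)


@dataclass(frozen=True)
class Epoch:
    """One labeled 2 s window of multichannel EEG.

    ``window`` holds the half-open time span in seconds relative to the
    anchor sample; the anchor itself (time 0) is excluded.
    """

    epoch_id: str
    label: str
    data: np.ndarray  # channels x samples, µV
    recording_id: str
    anchor: int
    window: tuple[float, float]
    participant_id: str = ""
    session_day: int = 0
    group: str = ""
    movement_type: str = ""

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Labeled epochs of one recording plus rejection bookkeeping."""

    epochs: list[Epoch]
    channel_labels: tuple[str, ...]
    sampling_rate: float
    rejected_count: dict[str, int] = field(default_factory=dict)
    balanced: bool = False

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def by_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]

    def count(self, label: str) -> int:
        return sum(1 for e in self.epochs if e.label == label)

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.epochs])

    @property
    def ids(self) -> list[str]:
        return [e.epoch_id for e in self.epochs]


def _cut(
    recording: ContinuousRecording,
    eeg: np.ndarray,
    anchor: int,
    start_s: float,
    end_s: float,
    label: str,
    index: int,
) -> Epoch | None:
    fs = recording.sampling_rate
    start = anchor + int(round(start_s * fs))
    end = anchor + int(round(end_s * fs))
    if start < 0 or end > eeg.shape[1]:
        logger.warning(
            "skipping %s epoch at sample %d of %s: window [%d, %d) outside recording",
            label,
            anchor,
            recording.recording_id,
            start,
            end,
        )
        return None
    tag = "mov" if label == MOVEMENT_LABEL else "idl"
    return Epoch(
        epoch_id=f"{recording.recording_id}-{tag}{index:03d}",
        label=label,
        data=eeg[:, start:end].copy(),
        recording_id=recording.recording_id,
        anchor=anchor,
        window=(start_s, end_s),
        participant_id=recording.participant_id,
        session_day=recording.session_day,
        group=recording.group,
        movement_type=recording.movement_type,
    )


def extract_epochs(
    recording: ContinuousRecording,
    onsets: Sequence[int] | None = None,
    idle_policy: Literal["idle_blocks", "pre_cue_window"] = "idle_blocks",
    filtered_eeg: np.ndarray | None = None,
) -> EpochSet:
    """Cut labeled epochs out of a (filtered) continuous recording.

    Movement epochs span [-2, 0) s around each onset.  Idle epochs either
    tile the recording's idle blocks with non-overlapping 2 s windows
    (``idle_blocks``) or take the [-5, -3) s window before each onset
    (``pre_cue_window``).  Onsets too close to the recording start are
    skipped with a warning rather than aborting the recording.
    """
    if onsets is None:
        onsets = recording.true_onsets
    if filtered_eeg is None:
        filtered_eeg = recording.eeg()
    fs = recording.sampling_rate
    n_epoch = int(round(EPOCH_DURATION_S * fs))
    if idle_policy not in ("idle_blocks", "pre_cue_window"):
        raise ConfigError(f"unknown idle_policy {idle_policy!r}")
    if idle_policy == "idle_blocks" and not recording.idle_intervals:
        raise ConfigError(
            f"idle_policy='idle_blocks' but {recording.recording_id} has no idle intervals"
        )

    epochs: list[Epoch] = []
    for i, onset in enumerate(onsets):
        cut = _cut(recording, filtered_eeg, int(onset), -2.0, 0.0, MOVEMENT_LABEL, i)
        if cut is not None:
            epochs.append(cut)

    idle_count = 0
    if idle_policy == "pre_cue_window":
        for onset in onsets:
            cut = _cut(recording, filtered_eeg, int(onset), -5.0, -3.0, IDLE_LABEL, idle_count)
            if cut is not None:
                epochs.append(cut)
                idle_count += 1
    else:
        for start, end in recording.idle_intervals:
            anchor = start
            while anchor + n_epoch <= end:
                cut = _cut(recording, filtered_eeg, anchor, 0.0, EPOCH_DURATION_S, IDLE_LABEL, idle_count)
                if cut is not None:
                    epochs.append(cut)
                    idle_count += 1
                anchor += n_epoch

    return EpochSet(
        epochs=epochs,
        channel_labels=tuple(recording.eeg_channels),
        sampling_rate=fs,
    )


def reject_artifacts(epochs: EpochSet, threshold: float = DEFAULT_REJECT_UV) -> EpochSet:
    """Drop every epoch whose absolute amplitude exceeds ``threshold`` µV
    on any channel at any sample; rejected counts are recorded per label."""
    kept: list[Epoch] = []
    rejected = dict(epochs.rejected_count)
    for epoch in epochs:
        if np.any(np.abs(epoch.data) > threshold):
            rejected[epoch.label] = rejected.get(epoch.label, 0) + 1
        else:
            kept.append(epoch)
    rejected.setdefault(MOVEMENT_LABEL, 0)
    rejected.setdefault(IDLE_LABEL, 0)
    return EpochSet(
        epochs=kept,
        channel_labels=epochs.channel_labels,
        sampling_rate=epochs.sampling_rate,
        rejected_count=rejected,
        balanced=epochs.balanced,
    )


def balance_classes(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Equalize the class counts by seeded uniform subsampling (without
    replacement) of the surplus class; epochs are never fabricated."""
    movement = epochs.by_label(MOVEMENT_LABEL)
    idle = epochs.by_label(IDLE_LABEL)
    if not movement or not idle:
        ref = epochs.epochs[0].recording_id if epochs.epochs else "<empty>"
        raise BalanceError(
            f"cannot balance classes for {ref}: "
            f"{len(movement)} movement vs {len(idle)} idle epochs"
        )
    n = min(len(movement), len(idle))
    rng = np.random.default_rng(seed)

    def subsample(pool: list[Epoch]) -> list[Epoch]:
        if len(pool) == n:
            return pool
        keep = rng.choice(len(pool), size=n, replace=False)
        keep.sort()
        return [pool[i] for i in keep]

    balanced = subsample(movement) + subsample(idle)
    return EpochSet(
        epochs=balanced,
        channel_labels=epochs.channel_labels,
        sampling_rate=epochs.sampling_rate,
        rejected_count=dict(epochs.rejected_count),
        balanced=True,
    )


def preprocess_recording(
    recording: ContinuousRecording,
    onsets: Sequence[int] | None = None,
    idle_policy: Literal["idle_blocks", "pre_cue_window"] | None = None,
    reject_uv: float = DEFAULT_REJECT_UV,
    balance_seed: int = 0,
    eeg_filter: FilterSpec = EEG_FILTER,
) -> EpochSet:
    """Full per-recording pipeline: zero-phase EEG band-pass, epoch
    extraction, amplitude-based rejection, and class balancing.

    The idle policy defaults to the study convention: dedicated idle
    blocks when the recording has them, otherwise the pre-cue window.
    """
    if idle_policy is None:
        idle_policy = "idle_blocks" if recording.idle_intervals else "pre_cue_window"
    filtered = bandpass_filter(recording.eeg(), eeg_filter, recording.sampling_rate)
    epochs = extract_epochs(recording, onsets, idle_policy, filtered_eeg=filtered)
    epochs = reject_artifacts(epochs, reject_uv)
    return balance_classes(epochs, seed=balance_seed)
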