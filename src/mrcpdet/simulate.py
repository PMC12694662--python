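"""Synthetic continuous EEG/EMG generator.

Each recording is one session of one participant performing one movement
type: a lead-in, a block of cue-paced trials (one cue every
``inter_trial_interval`` seconds), and a closing idle block.  The EEG on
every channel is the sum of

* 1/f (pink) broadband background noise,
* a band-limited 8-30 Hz oscillation whose amplitude is attenuated by the
  participant's ERD depth throughout the 2 s window preceding each
  movement onset, and
* the movement-related cortical potential (MRCP): a smooth negative
  half-cosine ramp peaking at the onset sample, followed by an exponential
  return to baseline.

True movement onsets (cue + reaction latency + jitter) are stored next to
the cue triggers so that EMG onset-detection accuracy is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import EEG_CHANNELS, ParticipantProfile, SimulationConfig, sample_profile
from .errors import ConfigError, SizingError

__all__ = [
    "ContinuousRecording",
    "MrcpWaveform",
    "mrcp_waveform",
    "generate_session",
    "generate_cohort",
    "pink_noise",
]

_ERD_RAMP_S = 0.1  # attenuation ramp placed just before the scored window
_ERD_RECOVERY_S = 0.5  # gain recovery after movement onset


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with its event annotations.

    ``signal`` is channels x samples in µV.  ``true_onsets`` is ground
    truth available only for synthetic data; real exports may carry cue
    triggers only.  ``idle_intervals`` are half-open ``[start, end)``
    sample spans guaranteed to contain neither MRCP nor ERD.
    """

    channel_labels: tuple[str, ...]
    sampling_rate: float
    signal: np.ndarray
    cue_events: np.ndarray
    true_onsets: np.ndarray
    idle_intervals: list[tuple[int, int]]
    participant_id: str
    session_day: int
    group: str
    movement_type: str

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.cue_events = np.asarray(self.cue_events, dtype=int)
        self.true_onsets = np.asarray(self.true_onsets, dtype=int)
        n = self.n_samples
        for name, events in (("cue_events", self.cue_events), ("true_onsets", self.true_onsets)):
            if events.size and (events.min() < 0 or events.max() >= n):
                raise ConfigError(f"{name} contains indices outside [0, {n})")
        if self.cue_events.size > 1 and np.any(np.diff(self.cue_events) <= 0):
            raise ConfigError("cue_events must be strictly increasing")
        for start, end in self.idle_intervals:
            if not 0 <= start < end <= n:
                raise ConfigError(f"idle interval [{start}, {end}) outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def recording_id(self) -> str:
        return f"{self.participant_id}-d{self.session_day}-{self.movement_type}"

    @property
    def eeg_channels(self) -> list[str]:
        return [c for c in self.channel_labels if c in EEG_CHANNELS]

    @property
    def emg_channels(self) -> list[str]:
        return [c for c in self.channel_labels if c.startswith("EMG")]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.signal[self.channel_labels.index(label)]
        except ValueError:
            raise ConfigError(f"recording has no channel {label!r}") from None

    def eeg(self) -> np.ndarray:
        idx = [self.channel_labels.index(c) for c in self.eeg_channels]
        return self.signal[idx]


@dataclass(frozen=True)
class MrcpWaveform:
    """Per-channel MRCP kernel; ``onset_index`` marks time zero."""

    data: np.ndarray  # channels x samples, µV
    onset_index: int
    sampling_rate: float


def mrcp_waveform(
    profile: ParticipantProfile,
    sampling_rate: float,
    movement: str | None = None,
) -> MrcpWaveform:
    """Build the noiseless MRCP kernel of one participant.

    A half-cosine negative ramp spans the final ``ramp_duration`` seconds
    before onset, reaching ``-peak_amplitude`` (times the channel weight)
    exactly at the onset sample, then relaxes back to baseline
    exponentially with time constant ``rebound_tau``.
    """
    if profile.ramp_duration > 2.0:
        raise ConfigError(f"ramp_duration must be <= 2 s, got {profile.ramp_duration!r}")
    if movement is None:
        movement = next(iter(profile.peak_amplitude))
    amplitude = profile.amplitude(movement)
    fs = float(sampling_rate)
    n_pre = int(round(profile.ramp_duration * fs))
    n_post = int(round(6.0 * profile.rebound_tau * fs))
    t_pre = np.arange(-n_pre, 0) / fs
    t_post = np.arange(0, n_post + 1) / fs
    ramp = -0.5 * (1.0 + np.cos(np.pi * t_pre / profile.ramp_duration))
    rebound = -np.exp(-t_post / profile.rebound_tau)
    shape = np.concatenate([ramp, rebound])
    weights = np.asarray(profile.channel_weights)
    data = amplitude * weights[:, None] * shape[None, :]
    return MrcpWaveform(data=data, onset_index=n_pre, sampling_rate=fs)


def pink_noise(rng: np.random.Generator, n_samples: int, std: float) -> np.ndarray:
    """Gaussian 1/f noise with the requested standard deviation."""
    if std == 0 or n_samples == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spectrum * scale, n=n_samples)
    return std * shaped / shaped.std()


def _band_oscillation(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    rms: float,
    freqs: Sequence[float],
) -> np.ndarray:
    """Band-limited 8-30 Hz activity at the participant's trait
    frequencies, with phases drawn fresh per channel and session."""
    if rms == 0 or not len(freqs):
        return np.zeros(n_samples)
    t = np.arange(n_samples) / fs
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    amp = rms * np.sqrt(2.0 / len(freqs))
    osc = np.zeros(n_samples)
    for f, ph in zip(freqs, phases):
        osc += amp * np.sin(2.0 * np.pi * f * t + ph)
    return osc


def _erd_envelope(
    n_samples: int, fs: float, onsets: Sequence[int], depth: float
) -> np.ndarray:
    """Multiplicative gain applied to the oscillatory component.

    Gain drops to ``1 - depth`` over a short ramp that ends 2 s before
    each onset, holds through the whole [-2, 0) s pre-movement window, and
    recovers after the onset.  The ramps live outside the scored window so
    a depth of 1 silences the oscillation in the entire window.
    """
    gain = np.ones(n_samples)
    if depth == 0 or not len(onsets):
        return gain
    n_pre = int(round(2.0 * fs))
    n_ramp = max(1, int(round(_ERD_RAMP_S * fs)))
    n_rec = max(1, int(round(_ERD_RECOVERY_S * fs)))
    down = 1.0 - depth * 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    up = 1.0 - depth * 0.5 * (1.0 + np.cos(np.pi * np.arange(n_rec) / n_rec))
    for onset in onsets:
        lo = onset - n_pre - n_ramp
        for offset, seg in ((lo, down), (onset - n_pre, np.full(n_pre, 1.0 - depth)), (onset, up)):
            a = max(0, offset)
            b = min(n_samples, offset + len(seg))
            if a < b:
                gain[a:b] = np.minimum(gain[a:b], seg[a - offset : b - offset])
    return gain


def _emg_trace(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    onsets: Sequence[int],
    config: SimulationConfig,
) -> np.ndarray:
    """Surface-EMG model: Gaussian baseline plus 60-150 Hz bursts at onsets."""
    from scipy import signal as sps

    trace = rng.standard_normal(n_samples) * config.emg_baseline_std
    n_burst = int(round(config.emg_burst_duration * fs))
    if n_burst == 0 or config.emg_burst_gain == 0:
        return trace
    high = min(150.0, 0.45 * fs)
    sos = sps.butter(4, [60.0, high], btype="band", fs=fs, output="sos")
    window = np.hanning(max(n_burst // 4, 3))
    for onset in onsets:
        end = min(n_samples, onset + n_burst)
        if onset >= n_samples or end <= onset:
            continue
        burst = sps.sosfilt(sos, rng.standard_normal(n_burst))
        std = burst.std()
        if std > 0:
            burst = burst / std * (config.emg_burst_gain * config.emg_baseline_std)
        # soft edges to avoid broadband clicks
        n_edge = len(window) // 2
        burst[:n_edge] *= window[:n_edge]
        burst[-n_edge:] *= window[-n_edge:]
        trace[onset:end] += burst[: end - onset]
    return trace


def _session_rng(config: SimulationConfig, profile: ParticipantProfile, session_day: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, tag, profile.participant_index, session_day]
    )


def generate_session(
    profile: ParticipantProfile,
    session_day: int,
    config: SimulationConfig,
    movement: str | None = None,
) -> ContinuousRecording:
    """Synthesize one continuous session recording.

    Layout: ``lead_in`` seconds of rest, ``trials_per_movement`` cue-paced
    trials, a 2 s gap, then an idle block of ``idle_block_duration``
    seconds.  Session-level drift perturbs the MRCP amplitude (additive,
    ``session_drift_std``) and the per-channel gains (multiplicative).
    """
    if movement is None:
        movement = config.movement_types[0]
    fs = config.sampling_rate
    n_trials = config.trials_per_movement
    required = (
        config.lead_in
        + n_trials * config.inter_trial_interval
        + 2.0
        + config.idle_block_duration
        + 2.0
    )
    duration = config.recording_duration if config.recording_duration is not None else required
    if duration < required:
        raise SizingError(
            f"{n_trials} trials at {config.inter_trial_interval} s spacing plus a "
            f"{config.idle_block_duration} s idle block need {required:.1f} s; "
            f"recording_duration is {duration:.1f} s"
        )
    n_samples = int(round(duration * fs))

    rng = _session_rng(config, profile, session_day, 0xA11CE)
    # session-level drift, shared by all channels
    amp_shift = rng.normal(0.0, config.session_drift_std)
    gains = rng.normal(1.0, config.channel_gain_drift_std, size=len(EEG_CHANNELS))
    gains = np.clip(gains, 0.1, None)

    cues = (config.lead_in + np.arange(n_trials) * config.inter_trial_interval) * fs
    cues = np.round(cues).astype(int)
    jitter = rng.normal(0.0, config.onset_jitter_std, size=n_trials)
    onsets = cues + np.round((profile.reaction_latency + jitter) * fs).astype(int)
    onsets = np.clip(onsets, 0, n_samples - 1)

    idle_start = int(round((config.lead_in + n_trials * config.inter_trial_interval + 2.0) * fs))
    idle_end = min(n_samples, idle_start + int(round(config.idle_block_duration * fs)))
    idle_intervals = [(idle_start, idle_end)] if idle_end > idle_start else []

    # drift perturbs an existing MRCP; a zero-amplitude (no-signal) profile
    # stays signal-free rather than acquiring an MRCP from the drift draw
    base_amplitude = profile.amplitude(movement)
    amplitude = max(0.0, base_amplitude + amp_shift) if base_amplitude > 0 else 0.0
    drifted = ParticipantProfile(
        participant_index=profile.participant_index,
        participant_id=profile.participant_id,
        peak_amplitude={movement: amplitude},
        channel_weights=profile.channel_weights,
        ramp_duration=profile.ramp_duration,
        rebound_tau=profile.rebound_tau,
        erd_depth=profile.erd_depth,
        osc_amplitude=profile.osc_amplitude,
        osc_freqs=profile.osc_freqs,
        noise_std=profile.noise_std,
        reaction_latency=profile.reaction_latency,
    )
    kernel = mrcp_waveform(drifted, fs, movement)

    envelope = _erd_envelope(n_samples, fs, onsets, profile.erd_depth)
    n_eeg = len(EEG_CHANNELS)
    eeg = np.zeros((n_eeg, n_samples))
    freq_jitter = rng.normal(0.0, config.session_freq_jitter_std, size=len(profile.osc_freqs))
    session_freqs = np.clip(np.asarray(profile.osc_freqs) + freq_jitter, 8.0, 30.0)
    for ch in range(n_eeg):
        background = pink_noise(rng, n_samples, profile.noise_std)
        osc = _band_oscillation(rng, n_samples, fs, profile.osc_amplitude, session_freqs)
        eeg[ch] = background + envelope * osc
    for onset in onsets:
        lo = onset - kernel.onset_index
        hi = lo + kernel.data.shape[1]
        a, b = max(0, lo), min(n_samples, hi)
        if a < b:
            eeg[:, a:b] += kernel.data[:, a - lo : b - lo]
    eeg = gains[:, None] * eeg

    labels = list(EEG_CHANNELS)
    channels = [eeg]
    if config.include_emg:
        labels.append(f"EMG_{movement}")
        channels.append(_emg_trace(rng, n_samples, fs, onsets, config)[None, :])
    signal = np.vstack(channels)

    return ContinuousRecording(
        channel_labels=tuple(labels),
        sampling_rate=fs,
        signal=signal,
        cue_events=cues,
        true_onsets=onsets,
        idle_intervals=idle_intervals,
        participant_id=profile.participant_id,
        session_day=session_day,
        group=config.group,
        movement_type=movement,
    )


def generate_cohort(config: SimulationConfig) -> list[ContinuousRecording]:
    """Generate the full cohort: one recording per participant, session
    day, and movement type.  Participant random effects are drawn once and
    shared across that participant's sessions; the whole cohort is a pure
    function of the configuration (including its seed)."""
    recordings: list[ContinuousRecording] = []
    for p in range(config.n_participants):
        profile = sample_profile(config, p)
        for day in range(1, config.sessions_per_participant + 1):
            for movement in config.movement_types:
                recordings.append(generate_session(profile, day, config, movement))
    return recordings
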