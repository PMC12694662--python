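"""Simulation configuration and participant-level random effects.

The synthetic cohorts emulate cue-paced ballistic movements recorded over
sensorimotor cortex: a slow negative movement-related cortical potential
(MRCP) builds up before each movement onset, 8-30 Hz oscillatory power
desynchronizes (ERD) in the pre-movement window, and surface EMG shows a
burst at onset.  Participant- and session-level random effects give the
cohorts the variance structure that makes cross-session and cross-subject
classifier calibration harder than within-session calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ConfigError

EEG_CHANNELS: tuple[str, ...] = ("C3", "C1", "Cz", "C2", "C4")
MOVEMENT_TYPES: tuple[str, ...] = ("wrist", "ankle")
GROUPS: tuple[str, ...] = ("CP", "able_bodied")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic EEG/EMG generator.

    Amplitudes are in microvolts (negative-going MRCP peaks are given as
    positive magnitudes), durations in seconds, rates in Hz.
    ``mrcp_peak_amplitude_mean`` may be a scalar (applied to every movement
    type) or a mapping ``{movement_type: magnitude}``.
    """

    n_participants: int = 1
    sessions_per_participant: int = 1
    trials_per_movement: int = 50
    movement_types: tuple[str, ...] = ("wrist",)
    group: str = "able_bodied"
    sampling_rate: float = 512.0
    inter_trial_interval: float = 10.0
    mrcp_peak_amplitude_mean: float | Mapping[str, float] = 10.0
    mrcp_amplitude_cv: float = 0.4
    mrcp_ramp_duration: float = 1.5
    mrcp_rebound_tau: float = 0.3
    erd_depth: float = 0.4
    osc_amplitude: float = 4.0
    noise_std: float = 10.0
    session_drift_std: float = 2.0
    channel_gain_drift_std: float = 0.1
    session_freq_jitter_std: float = 0.3
    onset_jitter_std: float = 0.1
    reaction_latency_mean: float = 0.2
    reaction_latency_std: float = 0.05
    idle_block_duration: float = 180.0
    lead_in: float = 10.0
    include_emg: bool = True
    emg_baseline_std: float = 1.0
    emg_burst_gain: float = 10.0
    emg_burst_duration: float = 0.3
    recording_duration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "sessions_per_participant", "trials_per_movement"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        if self.sampling_rate <= 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate!r}")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigError(f"erd_depth must lie in [0, 1], got {self.erd_depth!r}")
        if self.mrcp_amplitude_cv < 0:
            raise ConfigError(f"mrcp_amplitude_cv must be >= 0, got {self.mrcp_amplitude_cv!r}")
        if not 0 < self.mrcp_ramp_duration <= 2.0:
            raise ConfigError(
                f"mrcp_ramp_duration must lie in (0, 2] s, got {self.mrcp_ramp_duration!r}"
            )
        if self.mrcp_rebound_tau <= 0:
            raise ConfigError(f"mrcp_rebound_tau must be > 0, got {self.mrcp_rebound_tau!r}")
        if not self.movement_types:
            raise ConfigError("movement_types must be a non-empty subset of " f"{MOVEMENT_TYPES}")
        for movement in self.movement_types:
            if movement not in MOVEMENT_TYPES:
                raise ConfigError(
                    f"movement_types contains {movement!r}; allowed: {MOVEMENT_TYPES}"
                )
        if self.group not in GROUPS:
            raise ConfigError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name in (
            "inter_trial_interval",
            "osc_amplitude",
            "idle_block_duration",
            "lead_in",
            "emg_baseline_std",
            "emg_burst_gain",
            "emg_burst_duration",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        for name in (
            "noise_std",
            "session_drift_std",
            "channel_gain_drift_std",
            "session_freq_jitter_std",
            "onset_jitter_std",
            "reaction_latency_std",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.inter_trial_interval < self.mrcp_ramp_duration + 2.0:
            raise ConfigError(
                "inter_trial_interval must leave room for a full pre-movement window "
                f"(>= mrcp_ramp_duration + 2 s), got {self.inter_trial_interval!r}"
            )
        for movement in self.movement_types:
            if self.amplitude_mean(movement) < 0:
                raise ConfigError(
                    f"mrcp_peak_amplitude_mean[{movement!r}] must be >= 0 "
                    "(magnitude of the negative peak)"
                )

    def amplitude_mean(self, movement: str) -> float:
        """Mean MRCP peak magnitude (µV) for one movement type."""
        if isinstance(self.mrcp_peak_amplitude_mean, Mapping):
            try:
                return float(self.mrcp_peak_amplitude_mean[movement])
            except KeyError:
                raise ConfigError(
                    f"mrcp_peak_amplitude_mean has no entry for movement {movement!r}"
                ) from None
        return float(self.mrcp_peak_amplitude_mean)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    @classmethod
    def able_bodied_study(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Cohort preset mirroring the able-bodied arm of the study design:
        15 participants, 3 sessions, 50 cued wrist extensions per session,
        MRCP peak near 10 µV."""
        params = dict(
            n_participants=15,
            sessions_per_participant=3,
            trials_per_movement=50,
            movement_types=("wrist",),
            group="able_bodied",
            mrcp_peak_amplitude_mean=10.0,
            include_emg=False,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def cp_study(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Cohort preset mirroring the cerebral-palsy arm: wrist and ankle
        movements, MRCP peaks near 5 µV (wrist) and 10 µV (ankle), EMG
        recorded for onset detection."""
        params = dict(
            n_participants=5,
            sessions_per_participant=2,
            trials_per_movement=50,
            movement_types=("wrist", "ankle"),
            group="CP",
            mrcp_peak_amplitude_mean={"wrist": 5.0, "ankle": 10.0},
            include_emg=True,
            onset_jitter_std=0.2,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant realization of the cohort random effects.

    Drawn once per participant and reused for all of that participant's
    sessions; session-level drift is applied on top at generation time.
    ``peak_amplitude`` maps movement type -> peak magnitude (µV);
    ``channel_weights`` scales the MRCP across the five EEG channels
    (largest weight 1 at the peak channel).
    """

    participant_index: int
    participant_id: str
    peak_amplitude: Mapping[str, float]
    channel_weights: tuple[float, ...]
    ramp_duration: float
    rebound_tau: float
    erd_depth: float
    osc_amplitude: float
    osc_freqs: tuple[float, ...]
    noise_std: float
    reaction_latency: float

    def amplitude(self, movement: str) -> float:
        try:
            return float(self.peak_amplitude[movement])
        except KeyError:
            raise ConfigError(f"profile has no amplitude for movement {movement!r}") from None


def _lognormal_scale(rng: np.random.Generator, cv: float) -> float:
    """One multiplicative draw with unit mean and coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def sample_profile(config: SimulationConfig, participant_index: int) -> ParticipantProfile:
    """Draw the random effects of one participant.

    Deterministic given ``(config.seed, participant_index)``.  Peak
    amplitudes follow a log-normal law with the configured mean and
    between-participant coefficient of variation; a single participant
    scale multiplies every movement type so that limb effects stay
    consistent within a participant.
    """
    if not 0 <= participant_index < config.n_participants:
        raise ConfigError(
            f"participant_index must lie in [0, {config.n_participants}), "
            f"got {participant_index!r}"
        )
    rng = np.random.default_rng([config.seed, 0x5EED, participant_index])
    cv = config.mrcp_amplitude_cv
    amp_scale = _lognormal_scale(rng, cv)
    amplitudes = {m: config.amplitude_mean(m) * amp_scale for m in config.movement_types}

    # Channel topography: flat in expectation (peak similar at Cz and C3),
    # jittered per participant with a spread tied to the amplitude CV so the
    # zero-variance configuration stays exactly deterministic.
    weights = np.ones(len(EEG_CHANNELS))
    if cv > 0:
        weights = weights * np.array(
            [_lognormal_scale(rng, 0.3 * cv) for _ in EEG_CHANNELS]
        )
        weights = weights / weights.max()

    # mrcp_amplitude_cv acts as the master between-participant heterogeneity
    # knob: cv = 0 yields a perfectly homogeneous cohort.  Morphology
    # (time-to-peak ramp), ERD depth and background level all vary across
    # participants so that cross-subject transfer is genuinely harder than
    # cross-session transfer.
    hetero = 1.0 if cv > 0 else 0.0
    ramp_sd = 0.2 * config.mrcp_ramp_duration * hetero
    ramp = float(np.clip(rng.normal(config.mrcp_ramp_duration, ramp_sd), 0.5, 2.0))
    erd = float(np.clip(config.erd_depth * _lognormal_scale(rng, 0.3 * hetero), 0.0, 1.0))
    noise = config.noise_std * _lognormal_scale(rng, 0.35 * hetero)
    osc = config.osc_amplitude * _lognormal_scale(rng, 0.25 * hetero)
    latency = float(
        max(0.0, rng.normal(config.reaction_latency_mean, config.reaction_latency_std))
    )
    # Oscillation peak frequencies are stable individual traits (cf. the
    # individual alpha frequency): drawn once per participant and reused
    # across sessions.
    osc_freqs = tuple(float(f) for f in np.sort(rng.uniform(8.0, 30.0, size=10)))
    prefix = "AB" if config.group == "able_bodied" else "CP"
    return ParticipantProfile(
        participant_index=participant_index,
        participant_id=f"{prefix}{participant_index:02d}",
        peak_amplitude=amplitudes,
        channel_weights=tuple(float(w) for w in weights),
        ramp_duration=ramp,
        rebound_tau=config.mrcp_rebound_tau,
        erd_depth=erd,
        osc_amplitude=float(osc),
        osc_freqs=osc_freqs,
        noise_std=float(noise),
        reaction_latency=latency,
    )
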