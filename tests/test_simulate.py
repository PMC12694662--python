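"""Synthetic-data generator: waveform shape, session structure,
random-effects laws and determinism."""

import numpy as np
import pytest

from mrcpdet import (
    SimulationConfig,
    generate_cohort,
    generate_session,
    mrcp_waveform,
    sample_profile,
    spectral_features,
    prepare_session,
)
from mrcpdet.errors import ConfigError, SizingError

FS = 512.0


def small_config(**over):
    base = dict(
        n_participants=1,
        sessions_per_participant=1,
        trials_per_movement=5,
        idle_block_duration=20.0,
        seed=0,
    )
    base.update(over)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_participants", 0),
            ("trials_per_movement", -1),
            ("sampling_rate", 0.0),
            ("erd_depth", 1.5),
            ("mrcp_amplitude_cv", -0.1),
            ("mrcp_ramp_duration", 2.5),
            ("group", "healthy"),
            ("movement_types", ("elbow",)),
        ],
    )
    def test_invalid_field_raises_and_names_field(self, field, value):
        with pytest.raises(ConfigError) as err:
            small_config(**{field: value})
        assert field.split("_")[0] in str(err.value) or field in str(err.value)

    def test_amplitude_mapping_missing_movement(self):
        cfg = small_config(mrcp_peak_amplitude_mean={"wrist": 5.0})
        with pytest.raises(ConfigError):
            cfg.amplitude_mean("ankle")


class TestParticipantProfiles:
    def test_zero_cv_gives_exact_mean_amplitude(self):
        cfg = small_config(mrcp_amplitude_cv=0.0, mrcp_peak_amplitude_mean=7.5)
        for i in range(3):
            profile = sample_profile(small_config(n_participants=3, mrcp_amplitude_cv=0.0,
                                                  mrcp_peak_amplitude_mean=7.5), i)
            assert profile.amplitude("wrist") == 7.5
            assert profile.channel_weights == (1.0,) * 5

    def test_profile_deterministic_given_seed_and_index(self):
        cfg = small_config(n_participants=2)
        assert sample_profile(cfg, 1) == sample_profile(cfg, 1)

    def test_amplitude_cv_matches_lognormal_law(self):
        # Monte-Carlo: 1000 participants at cv = 0.3 -> sample CV in [0.25, 0.35]
        cfg = small_config(n_participants=1000, mrcp_amplitude_cv=0.3, seed=2)
        amps = np.array([sample_profile(cfg, i).amplitude("wrist") for i in range(1000)])
        cv = amps.std() / amps.mean()
        assert 0.25 <= cv <= 0.35

    def test_index_out_of_range(self):
        with pytest.raises(ConfigError):
            sample_profile(small_config(), 1)


class TestMrcpWaveform:
    def test_zero_amplitude_is_identically_zero(self):
        cfg = small_config(mrcp_peak_amplitude_mean=0.0, mrcp_amplitude_cv=0.0)
        kernel = mrcp_waveform(sample_profile(cfg, 0), FS)
        assert np.all(kernel.data == 0)

    def test_peak_reaches_negative_amplitude_at_onset(self):
        cfg = small_config(mrcp_peak_amplitude_mean=10.0, mrcp_amplitude_cv=0.0)
        kernel = mrcp_waveform(sample_profile(cfg, 0), FS)
        assert kernel.data.min() == pytest.approx(-10.0, abs=1e-9)
        assert np.argmin(kernel.data[2]) == kernel.onset_index

    def test_baseline_two_seconds_before_onset(self):
        cfg = small_config(mrcp_peak_amplitude_mean=10.0, mrcp_amplitude_cv=0.0)
        profile = sample_profile(cfg, 0)
        kernel = mrcp_waveform(profile, FS)
        # waveform starts at the ramp onset (<= 2 s before the peak); value there ~ 0
        assert abs(kernel.data[2, 0]) <= 0.1

    def test_preonset_ramp_is_monotone_negative(self):
        cfg = small_config(mrcp_peak_amplitude_mean=5.0, mrcp_amplitude_cv=0.0)
        kernel = mrcp_waveform(sample_profile(cfg, 0), FS)
        pre = kernel.data[2, : kernel.onset_index + 1]
        assert np.all(np.diff(pre) <= 1e-12)

    def test_smoothness_no_step_discontinuities(self):
        cfg = small_config(mrcp_peak_amplitude_mean=10.0, mrcp_amplitude_cv=0.0)
        kernel = mrcp_waveform(sample_profile(cfg, 0), FS)
        steps = np.abs(np.diff(kernel.data[2]))
        # largest sample-to-sample step stays far below the peak amplitude
        assert steps.max() < 0.5


class TestGenerateSession:
    def test_cue_count_and_paced_duration(self):
        cfg = small_config(trials_per_movement=50, idle_block_duration=10.0)
        rec = generate_session(sample_profile(cfg, 0), 1, cfg)
        assert len(rec.cue_events) == 50
        assert rec.n_samples >= 500 * FS  # 50 trials at 10 s pacing

    def test_cue_spacing_at_least_inter_trial_interval(self):
        cfg = small_config(trials_per_movement=8)
        rec = generate_session(sample_profile(cfg, 0), 1, cfg)
        assert np.all(np.diff(rec.cue_events) >= cfg.inter_trial_interval * FS)

    def test_component_isolation_oscillation_only(self):
        cfg = small_config(
            noise_std=0.0,
            erd_depth=0.0,
            mrcp_peak_amplitude_mean=0.0,
            mrcp_amplitude_cv=0.0,
            session_drift_std=0.0,
            channel_gain_drift_std=0.0,
            include_emg=False,
        )
        rec = generate_session(sample_profile(cfg, 0), 1, cfg)
        # pure sum of sinusoids: band-limited, zero-mean, matched RMS
        x = rec.signal[0]
        assert abs(x.mean()) < 0.1
        assert x.std() == pytest.approx(cfg.osc_amplitude, rel=0.05)

    def test_full_erd_silences_preonset_band_power(self):
        cfg = small_config(
            noise_std=0.0,
            erd_depth=1.0,
            mrcp_peak_amplitude_mean=0.0,
            mrcp_amplitude_cv=0.0,
            include_emg=False,
        )
        rec = generate_session(sample_profile(cfg, 0), 1, cfg)
        for onset in rec.true_onsets:
            window = rec.signal[2, onset - int(2 * FS) : onset]
            assert np.abs(window).max() < 1e-9

    def test_requested_trials_must_fit(self):
        cfg = small_config(trials_per_movement=10, recording_duration=50.0)
        with pytest.raises(SizingError):
            generate_session(sample_profile(cfg, 0), 1, cfg)

    def test_event_indices_inside_recording(self):
        cfg = small_config()
        rec = generate_session(sample_profile(cfg, 0), 1, cfg)
        assert rec.true_onsets.min() >= 0
        assert rec.true_onsets.max() < rec.n_samples
        for start, end in rec.idle_intervals:
            assert 0 <= start < end <= rec.n_samples


class TestCohort:
    def test_cohort_size_matches_design(self):
        cfg = SimulationConfig(
            n_participants=15,
            sessions_per_participant=3,
            trials_per_movement=1,
            idle_block_duration=5.0,
            include_emg=False,
            seed=1,
        )
        assert len(generate_cohort(cfg)) == 45

    def test_single_participant_single_session(self):
        assert len(generate_cohort(small_config())) == 1

    def test_same_seed_bitwise_identical(self):
        cfg = small_config(trials_per_movement=3, idle_block_duration=10.0)
        a = generate_cohort(cfg)[0]
        b = generate_cohort(cfg)[0]
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.true_onsets, b.true_onsets)

    def test_movement_types_multiply_recordings(self):
        cfg = SimulationConfig(
            n_participants=2,
            sessions_per_participant=2,
            trials_per_movement=1,
            movement_types=("wrist", "ankle"),
            group="CP",
            mrcp_peak_amplitude_mean={"wrist": 5.0, "ankle": 10.0},
            idle_block_duration=5.0,
            seed=0,
        )
        recs = generate_cohort(cfg)
        assert len(recs) == 8
        assert {r.movement_type for r in recs} == {"wrist", "ankle"}


class TestStatisticalStructure:
    def test_idle_epochs_carry_no_mrcp_energy(self):
        cfg = small_config(
            trials_per_movement=20,
            idle_block_duration=60.0,
            noise_std=2.0,
            mrcp_peak_amplitude_mean=10.0,
            mrcp_amplitude_cv=0.0,
            session_drift_std=0.0,
            channel_gain_drift_std=0.0,
            seed=6,
        )
        ses = prepare_session(generate_cohort(cfg)[0])
        idle = ses.epochs.by_label("idle")
        grand = np.mean([e.data.mean() for e in idle])
        assert abs(grand) < 3 * cfg.noise_std / np.sqrt(len(idle))

    def test_erd_attenuates_band_power_by_depth_squared(self):
        depth = 0.5
        cfg = small_config(
            trials_per_movement=30,
            idle_block_duration=70.0,
            noise_std=0.0,
            erd_depth=depth,
            mrcp_peak_amplitude_mean=0.0,
            mrcp_amplitude_cv=0.0,
            seed=5,
        )
        rec = generate_cohort(cfg)[0]
        ses = prepare_session(rec)
        def mean_band_power(label):
            return np.mean(
                [spectral_features(e.data[2], FS).sum() for e in ses.epochs.by_label(label)]
            )
        ratio = mean_band_power("movement_intention") / mean_band_power("idle")
        assert ratio == pytest.approx((1 - depth) ** 2, rel=0.2)

    def test_grand_average_recovers_injected_amplitude(self):
        from mrcpdet import grand_average

        cfg = SimulationConfig(
            n_participants=3,
            sessions_per_participant=1,
            trials_per_movement=50,
            mrcp_peak_amplitude_mean=10.0,
            mrcp_amplitude_cv=0.0,
            noise_std=4.0,
            session_drift_std=0.0,
            channel_gain_drift_std=0.0,
            idle_block_duration=60.0,
            include_emg=False,
            seed=4,
        )
        per_part = {}
        for rec in generate_cohort(cfg):
            ses = prepare_session(rec)
            per_part.setdefault(rec.participant_id, []).extend(
                e.data for e in ses.epochs.by_label("movement_intention")
            )
        mean, _ = grand_average(per_part, channel=2)
        # MRCP amplitude convention: peak relative to the epoch-initial baseline
        baseline = mean[: int(0.25 * FS)].mean()
        peak = mean.min() - baseline
        assert peak == pytest.approx(-10.0, rel=0.15)
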