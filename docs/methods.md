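# Methods

`mrcpdet` detects single-trial movement intention from multichannel EEG by
classifying 2 s pre-movement epochs against idle epochs with a random
forest, and quantifies how the detector degrades when it is calibrated on
data from another day, another person, or another clinical population.
Because suitable clinical recordings are not publicly available, the
package ships a synthetic cohort generator whose statistical structure
carries the effects the analysis is about; everything downstream of the
generator treats its output exactly as it would treat a real export in
the same columnar format.

## Signal model

Each recording emulates one session of cue-paced ballistic movements:
five EEG channels (C3, C1, Cz, C2, C4) at 512 Hz, an optional bipolar EMG
channel, and a cue trigger every 10 s. Each EEG channel is the sum of
three components.

**MRCP.** The movement-related cortical potential is a smooth negative
deflection that builds up before a voluntary movement and peaks near its
onset. It is modelled as a half-cosine ramp over the final
`mrcp_ramp_duration` seconds (default 1.5 s) before the movement onset,
reaching `-A` µV exactly at the onset sample, followed by an exponential
return to baseline with time constant `mrcp_rebound_tau` (default
0.3 s). `A` defaults to 10 µV (able-bodied wrist, ankle) or 5 µV (CP
wrist); these magnitudes follow the grand-average amplitudes the analysis
is meant to recover. The kernel is identical on all channels up to
per-participant channel weights (flat in expectation — central-channel
amplitudes of pre-movement negativity are similar over the motor strip).

**Oscillatory background and ERD.** A band-limited 8–30 Hz process —
the sum of ten random-phase sinusoids with total RMS `osc_amplitude`
(default 4 µV) — represents sensorimotor rhythms. Its component
frequencies are drawn once per participant and reused across that
participant's sessions, emulating the stability of individual peak
frequencies (cf. the individual alpha frequency); sessions add a small
frequency jitter (`session_freq_jitter_std`, 0.3 Hz) and fresh phases.
Event-related desynchronization is a multiplicative gain dip: the
oscillation is attenuated by the participant's ERD depth (default 0.4)
throughout the entire [-2, 0) s pre-onset window, with the down-ramp
placed just *before* that window and the recovery just after it, so that
a depth of 1 silences the band completely inside the scored window.

**Broadband noise.** 1/f (pink) Gaussian noise with standard deviation
`noise_std` (default 10 µV) models the non-oscillatory EEG background.
There is no DC component; the 0.1 Hz high-pass in preprocessing is the
only detrending anywhere.

**EMG.** Baseline Gaussian noise plus a 0.3 s burst of 60–150 Hz
band-limited noise at 10x the baseline amplitude, starting at each true
movement onset. True onsets are cue + participant reaction latency +
trial-level jitter, and are stored in the recording metadata so onset
detection is measurable against ground truth.

## Random-effects structure

The calibration comparison only makes sense if the cohort has more
variance between participants than between a participant's sessions, and
more between sessions than within one. The generator encodes this as a
two-level hierarchy:

* **Participant level** (drawn once per participant): MRCP peak
  amplitude, log-normal with mean `mrcp_peak_amplitude_mean` and
  coefficient of variation `mrcp_amplitude_cv` (default 0.4); ramp
  duration (SD 20% of the mean); ERD depth, noise level and oscillation
  RMS (log-normal, CV 0.3/0.35/0.25); channel-weight jitter; oscillation
  trait frequencies; reaction latency. Setting `mrcp_amplitude_cv = 0`
  collapses the whole hierarchy to a homogeneous cohort — it is the
  single heterogeneity knob.
* **Session level** (drawn per session, on top of the profile): an
  additive amplitude shift (`session_drift_std`, default 2 µV),
  multiplicative per-channel gain perturbations
  (`channel_gain_drift_std`, default 0.1), oscillation frequency jitter
  and fresh phases. A profile with zero amplitude stays signal-free: the
  drift perturbs an existing MRCP rather than creating one, which keeps
  no-signal control conditions honest.

With these defaults the three same-group calibration scenarios order as
within-session > between-session > across-participant, which is the
qualitative phenomenon the evaluation is designed to exhibit; the margins
are a few accuracy points, as in comparable real cohorts.

## Preprocessing

EEG is band-passed 0.1–30 Hz with a 4th-order Butterworth applied
forward and backward (zero phase). Forward-backward filtering uses
reflection padding of three times the impulse-response scale of the
slowest corner (3·fs/f_low samples, capped at the signal length); the
0.1 Hz corner's transients last tens of seconds, so short default
paddings visibly distort the passband. EMG is band-passed 20–100 Hz,
notch-filtered 48–52 Hz, then full-wave rectified, in that order.

Movement-intention epochs cover [-2, 0) s around each onset (the onset
sample itself is time 0 and excluded; exactly 1024 samples at 512 Hz).
Idle epochs either tile dedicated idle blocks with non-overlapping 2 s
windows or take the [-5, -3) s pre-cue window, matching the two
conventions for patient and able-bodied recordings respectively. Epochs
with any sample exceeding 150 µV in magnitude on any channel are
rejected after filtering. The surplus class is then subsampled (seeded,
uniform, without replacement) so both classes have equal counts. No
baseline correction is applied to epochs.

## EMG onset detection

A double-threshold detector replaces interactive onset marking: the
rectified EMG is smoothed with a 50 ms moving average, and an onset is
the first sample of a run in which the smoothed envelope exceeds
(baseline mean + `k_sd` x baseline SD) for at least `min_duration_s`;
detections within `refractory_s` of a previous one are suppressed.
Defaults: baseline = first 5 s (the generator schedules no movement
there), k = 3, minimum duration 50 ms, refractory 5 s. The amplitude
threshold uses the *unsmoothed* rectified baseline's SD: the smoothed
envelope's SD is several times smaller, and a threshold based on it
produces occasional false detections in idle periods, while genuine
bursts (an order of magnitude above baseline) cross either threshold
immediately. `apply_overrides` provides the manual-correction hook
(add/remove indices, sorted and deduplicated) for onsets a reviewer
would amend.

## Features

Per channel of each 2 s epoch, 29 features in three families:

* **Temporal (5):** mean amplitude in the four consecutive 0.5 s
  windows, plus first-half mean minus second-half mean. The sign
  convention makes the half-difference positive for a negativity that
  deepens toward the anchor.
* **Spectral (23):** Welch power spectral density with a Hamming taper,
  1 s segments, 0.5 s overlap — the one segment length for which "1 Hz
  bins between 8 and 30 Hz" is exact: the PSD ordinates at 8, 9, …,
  30 Hz are the features (µV²/Hz, no log transform).
* **Template matching (1):** the zero-lag cross-correlation — the plain
  inner product, unnormalized and uncentered — between the epoch and the
  mean movement-intention waveform of the *training* epochs.

Columns follow `<channel>__tmp_w1..4`, `<channel>__tmp_halfdiff`,
`<channel>__spec_8..30`, `<channel>__xcorr0`, channel-major; five
channels give 145 features.

## Classification and calibration scenarios

A random forest with 128 trees (scikit-learn, unlimited depth, √p
feature subsampling, seeded) separates movement intention from idle.
Because the tree count is even, an exactly split ensemble vote is
resolved toward idle (P(movement) must exceed 0.5) — deterministic and
conservative against false activations. Features are not standardized;
forests are scale-invariant.

Four calibration scenarios: within-session (leave-one-sample-out CV
inside one session), between-session (train on the participant's other
sessions, each session tested once), across-participant
(leave-one-participant-out within one condition group and movement type,
scored per held-out session), across-condition (train on the entire
able-bodied cohort, test per CP participant, day and movement). The
template is refitted inside **every** fold from that fold's training
epochs only; each fold records the template's training-epoch fingerprint
so tests can assert that no test epoch ever contributed to the template.
Single-class training folds are recorded as fold errors and skipped,
never silently dropped.

## Evaluation

Confusion rates are percentages with movement intention as the positive
class; accuracy satisfies acc = (TPR·n₊ + TNR·n₋)/(n₊+n₋) by
construction. The chance level is the exact binomial inversion: the
smallest accuracy k/n whose right tail under Binomial(n, ½) is below
alpha (no normal approximation); when even n/n is not significant the
threshold is flagged unattainable. Grand averages are two-level:
participant means first, then mean and standard error across
participants. Display tables round half-away-from-zero with the
complementary cell adjusted so rows sum to 100; exports keep full
precision.

**MRCP amplitude convention.** Grand-average peak amplitudes are
measured relative to the epoch-initial baseline, the standard convention
for slow potentials. This matters here: the trial pacing (one movement
per 10 s) puts the fundamental of the periodic MRCP train exactly at the
0.1 Hz high-pass corner, which attenuates the raw minimum by roughly 20%
and shifts the inter-trial baseline positive. The baseline-referenced
peak recovers the injected amplitude within ±15%; the raw minimum does
not, for any implementation that filters as specified.

## Problem sizes and runtime choices

The 128-tree forest costs ~0.1 s per fit regardless of training-set
size, so leave-one-sample-out fold counts dominate runtime. The
scenario-ordering experiments therefore use 8 participants x 2 sessions
x 12 trials per movement (24 epochs per session), pooled over 10 seeds
in the test suite and 6 seeds in `scripts/acceptance.py`; separability
checks use one 50-trial session (100 LOSO folds). Temporal and spectral
features are cached per epoch across folds; only the template feature is
recomputed per fold.

## What the synthetic cohorts do and do not show

The generator reproduces the *structure* the analysis depends on: MRCP
morphology and amplitude scale, pre-movement band-power attenuation,
idle periods with neither, EMG bursts, and participant/session variance
ordering. It omits volume conduction, ocular and muscular artifacts
(artifact rejection is exercised with injected amplitude spikes),
non-stationary electrode impedance, and any realistic spatial covariance
between channels. Passing tests therefore demonstrate that the pipeline
is correct and that the calibration comparison behaves as designed under
the assumed variance structure — not that the specific accuracy numbers
would be attained on clinical recordings. Absolute synthetic accuracies
run higher than published patient values; the qualitative ordering of
calibration scenarios, not the absolute level, is the validated claim.

## Known limitations

* Offline analysis only: epochs are anchored on known onsets; no
  sliding-window online detection or decision thresholds.
* No spatial filtering (CSP/Laplacian), no re-referencing beyond the
  input, no ICA-style artifact correction.
* The exact double-threshold parameterization of interactive EMG
  toolboxes is not reproduced; detection is validated against synthetic
  ground truth only.
* Statistical comparison of scenarios (repeated-measures ANOVA etc.) is
  out of scope; the per-cell accuracy exports feed any external
  statistics tool.
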