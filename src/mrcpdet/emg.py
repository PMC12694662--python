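"""Double-threshold EMG onset detection.

Movement onsets are found on the conditioned (band-passed, notched,
rectified) EMG: a smoothed envelope must exceed an amplitude threshold
(baseline mean + k standard deviations) for a minimum duration before an
onset is declared, and further detections are suppressed for a refractory
period.  This is the programmatic stand-in for interactive inspection;
``apply_overrides`` provides the manual-correction hook.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, SizingError

__all__ = ["OnsetParams", "detect_onsets", "apply_overrides"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OnsetParams:
    """Double-threshold detector settings.

    ``baseline_window_s`` seconds at the start of the recording estimate
    the resting envelope statistics, so no movement may be scheduled
    there.  ``k_sd`` sets the amplitude threshold at baseline mean +
    k·SD; ``min_duration_s`` is the second (duration) threshold; after a
    detection, ``refractory_s`` seconds are blanked.
    """

    baseline_window_s: float = 5.0
    k_sd: float = 3.0
    min_duration_s: float = 0.05
    refractory_s: float = 5.0
    smoothing_s: float = 0.05

    def __post_init__(self) -> None:
        for name in ("baseline_window_s", "k_sd", "min_duration_s", "refractory_s", "smoothing_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.min_duration_s >= self.refractory_s:
            raise ConfigError(
                f"min_duration_s ({self.min_duration_s}) must be shorter than "
                f"refractory_s ({self.refractory_s})"
            )


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    # 'same' convolution keeps onsets aligned to within half the kernel
    return np.convolve(x, kernel, mode="same")


def detect_onsets(
    emg_rectified: np.ndarray,
    sampling_rate: float,
    params: OnsetParams = OnsetParams(),
) -> np.ndarray:
    """Detect movement onsets on conditioned EMG.

    Returns strictly increasing sample indices: the first sample of each
    run where the smoothed envelope stays above baseline mean + k·SD for
    at least ``min_duration_s``, with runs inside the refractory window of
    a previous detection suppressed.
    """
    x = np.asarray(emg_rectified, dtype=float)
    if x.ndim != 1:
        raise ConfigError("detect_onsets expects a single EMG channel")
    n_baseline = int(round(params.baseline_window_s * sampling_rate))
    if x.size < n_baseline:
        raise SizingError(
            f"recording of {x.size} samples is shorter than the "
            f"{params.baseline_window_s} s baseline window"
        )
    envelope = _smooth(x, int(round(params.smoothing_s * sampling_rate)))
    # amplitude threshold from the rectified (unsmoothed) baseline: its SD
    # is much larger than the smoothed envelope's, so envelope noise
    # excursions stay far below threshold while genuine bursts (an order
    # of magnitude above baseline) cross it immediately
    baseline = x[:n_baseline]
    threshold = baseline.mean() + params.k_sd * baseline.std()

    above = envelope > threshold
    min_run = max(1, int(round(params.min_duration_s * sampling_rate)))
    refractory = int(round(params.refractory_s * sampling_rate))

    # run-length encode the suprathreshold mask
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = edges[~above[edges]] + 1 if edges.size else np.array([], dtype=int)
    if above.size and above[0]:
        starts = np.concatenate([[0], starts])
    ends = edges[above[edges]] + 1 if edges.size else np.array([], dtype=int)
    if above.size and above[-1]:
        ends = np.concatenate([ends, [above.size]])

    onsets: list[int] = []
    last = -np.inf
    for start, end in zip(starts, ends):
        if end - start < min_run:
            continue
        if start - last < refractory:
            continue
        onsets.append(int(start))
        last = start
    return np.asarray(onsets, dtype=int)


def apply_overrides(
    onsets: np.ndarray,
    overrides: list[tuple[str, int]],
    n_samples: int | None = None,
) -> np.ndarray:
    """Apply manual onset corrections.

    ``overrides`` is a list of ``("add", index)`` / ``("remove", index)``
    pairs.  The result is sorted and deduplicated; removing an index that
    is not present is a warning, not an error.
    """
    current = set(int(v) for v in np.asarray(onsets, dtype=int))
    for action, index in overrides:
        index = int(index)
        if n_samples is not None and not 0 <= index < n_samples:
            raise ConfigError(f"override index {index} outside [0, {n_samples})")
        if action == "add":
            current.add(index)
        elif action == "remove":
            if index in current:
                current.remove(index)
            else:
                logger.warning("override: cannot remove absent onset %d", index)
        else:
            raise ConfigError(f"unknown override action {action!r}; use 'add' or 'remove'")
    return np.asarray(sorted(current), dtype=int)
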