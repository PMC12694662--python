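"""Per-channel feature families for single-trial epoch classification.

Three families are computed per EEG channel of each 2 s epoch:

* temporal (5): mean amplitude in the four consecutive 0.5 s windows plus
  the difference between the first- and second-half means (positive for a
  negative-going potential building toward the anchor);
* spectral (23): Welch power spectral density with a Hamming taper, 1 s
  segments and 0.5 s overlap, read off at the integer frequencies
  8..30 Hz (1 Hz bins);
* template matching (1): the zero-lag cross-correlation (unnormalized dot
  product) between the epoch and the mean movement-intention waveform of
  the training set.

With five channels this gives 5 x 29 = 145 features per epoch.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import SchemaError, ShapeError, TemplateError
from .preprocess import Epoch, EpochSet, MOVEMENT_LABEL

__all__ = [
    "FEATURE_FAMILIES",
    "Template",
    "temporal_features",
    "spectral_features",
    "build_template",
    "template_feature",
    "family_columns",
    "feature_columns",
    "assemble_features",
]

FEATURE_FAMILIES = ("temporal", "spectral", "template")
SPECTRAL_FREQS = tuple(range(8, 31))  # 23 one-hertz bins
N_FEATURES_PER_CHANNEL = 5 + len(SPECTRAL_FREQS) + 1


def _check_epoch_channel(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ShapeError(f"expected a 1-D channel waveform, got shape {x.shape}")
    expected = int(round(2.0 * sampling_rate))
    if x.size != expected:
        raise ShapeError(f"expected a 2 s epoch of {expected} samples, got {x.size}")
    return x


def temporal_features(epoch_channel: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Four 0.5 s window means plus the first-half minus second-half mean."""
    x = _check_epoch_channel(epoch_channel, sampling_rate)
    quarters = x.reshape(4, -1).mean(axis=1)
    half = x.size // 2
    halfdiff = x[:half].mean() - x[half:].mean()
    return np.concatenate([quarters, [halfdiff]])


def spectral_features(epoch_channel: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Welch PSD ordinates (µV²/Hz) at 8..30 Hz.

    1 s Hamming-tapered segments with 0.5 s overlap give a native 1 Hz
    resolution, so each 1 Hz bin is the single PSD ordinate at that
    integer frequency and a 2 s epoch yields exactly 23 values.
    """
    if sampling_rate < 64:
        raise ShapeError(f"sampling_rate must be >= 64 Hz, got {sampling_rate!r}")
    x = _check_epoch_channel(epoch_channel, sampling_rate)
    nperseg = int(round(sampling_rate))
    freqs, psd = sps.welch(
        x,
        fs=sampling_rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
    )
    idx = np.searchsorted(freqs, SPECTRAL_FREQS)
    if not np.allclose(freqs[idx], SPECTRAL_FREQS):
        raise ShapeError("PSD grid does not contain the integer frequencies 8..30 Hz")
    return psd[idx]


@dataclass(frozen=True)
class Template:
    """Mean movement-intention waveform of a training set.

    ``fingerprint`` is the sorted tuple of training-epoch ids; it lets
    tests audit that no test-fold epoch leaked into the template.
    """

    data: np.ndarray  # channels x samples, µV
    channel_labels: tuple[str, ...]
    sampling_rate: float
    n_training_epochs: int
    fingerprint: tuple[str, ...]

    @property
    def digest(self) -> str:
        joined = "\n".join(self.fingerprint).encode()
        return hashlib.sha256(joined).hexdigest()[:16]


def build_template(
    training_epochs: EpochSet | Sequence[Epoch],
    channel_labels: Sequence[str] = (),
    sampling_rate: float = 0.0,
) -> Template:
    """Point-wise mean across the training movement-intention epochs."""
    if isinstance(training_epochs, EpochSet):
        channel_labels = channel_labels or training_epochs.channel_labels
        sampling_rate = sampling_rate or training_epochs.sampling_rate
        training_epochs = training_epochs.epochs
    movement = [e for e in training_epochs if e.label == MOVEMENT_LABEL]
    if not movement:
        raise TemplateError("cannot build a template from zero movement-intention epochs")
    shapes = {e.data.shape for e in movement}
    if len(shapes) != 1:
        raise ShapeError(f"training epochs have inconsistent shapes: {sorted(shapes)}")
    stack = np.stack([e.data for e in movement])
    return Template(
        data=stack.mean(axis=0),
        channel_labels=tuple(channel_labels),
        sampling_rate=float(sampling_rate),
        n_training_epochs=len(movement),
        fingerprint=tuple(sorted(e.epoch_id for e in movement)),
    )


def template_feature(epoch_channel: np.ndarray, template_channel: np.ndarray) -> float:
    """Zero-lag cross-correlation: the plain inner product of epoch and
    template (unnormalized, uncentered)."""
    x = np.asarray(epoch_channel, dtype=float)
    t = np.asarray(template_channel, dtype=float)
    if x.shape != t.shape or x.ndim != 1:
        raise ShapeError(
            f"epoch and template must be 1-D and equally long, got {x.shape} vs {t.shape}"
        )
    return float(np.dot(x, t))


def family_columns(channel: str, family: str) -> list[str]:
    if family == "temporal":
        return [f"{channel}__tmp_w{i}" for i in range(1, 5)] + [f"{channel}__tmp_halfdiff"]
    if family == "spectral":
        return [f"{channel}__spec_{f}" for f in SPECTRAL_FREQS]
    if family == "template":
        return [f"{channel}__xcorr0"]
    raise SchemaError(f"unknown feature family {family!r}; allowed: {FEATURE_FAMILIES}")


def feature_columns(
    channel_labels: Iterable[str], families: Sequence[str] = FEATURE_FAMILIES
) -> list[str]:
    """Channel-major column order of the feature matrix."""
    for fam in families:
        if fam not in FEATURE_FAMILIES:
            raise SchemaError(f"unknown feature family {fam!r}; allowed: {FEATURE_FAMILIES}")
    columns: list[str] = []
    for channel in channel_labels:
        for family in FEATURE_FAMILIES:
            if family in families:
                columns.extend(family_columns(channel, family))
    return columns


def assemble_features(
    epochs: EpochSet | Sequence[Epoch],
    template: Template | None = None,
    families: Sequence[str] = FEATURE_FAMILIES,
    channel_labels: Sequence[str] | None = None,
    sampling_rate: float | None = None,
) -> pd.DataFrame:
    """Build the epochs x features table.

    Rows are indexed by epoch id and carry a ``label`` column; feature
    columns follow the ``<channel>__<family>`` naming convention in
    channel-major order.  The template family requires a ``template``
    fitted on training data disjoint from these epochs (enforced by the
    caller's fold plan and auditable via ``template.fingerprint``).
    """
    if isinstance(epochs, EpochSet):
        epoch_list = epochs.epochs
        channel_labels = channel_labels or epochs.channel_labels
        sampling_rate = sampling_rate or epochs.sampling_rate
    else:
        epoch_list = list(epochs)
    if channel_labels is None or sampling_rate is None:
        raise SchemaError("channel_labels and sampling_rate are required for bare epoch lists")
    if "template" in families and template is None:
        raise SchemaError("the 'template' family needs a fitted Template")
    if template is not None and template.data.shape[0] != len(channel_labels):
        raise SchemaError(
            f"template has {template.data.shape[0]} channels, epochs have {len(channel_labels)}"
        )
    columns = feature_columns(channel_labels, families)

    rows = np.empty((len(epoch_list), len(columns)))
    for i, epoch in enumerate(epoch_list):
        if epoch.data.shape[0] != len(channel_labels):
            raise SchemaError(
                f"epoch {epoch.epoch_id} has {epoch.data.shape[0]} channels, "
                f"expected {len(channel_labels)}"
            )
        values: list[np.ndarray | float] = []
        for c in range(len(channel_labels)):
            x = epoch.data[c]
            for family in FEATURE_FAMILIES:
                if family not in families:
                    continue
                if family == "temporal":
                    values.append(temporal_features(x, sampling_rate))
                elif family == "spectral":
                    values.append(spectral_features(x, sampling_rate))
                else:
                    values.append(template_feature(x, template.data[c]))
        rows[i] = np.hstack([np.atleast_1d(v) for v in values])
    if not np.all(np.isfinite(rows)):
        raise SchemaError("feature matrix contains non-finite values")

    frame = pd.DataFrame(rows, columns=columns, index=[e.epoch_id for e in epoch_list])
    frame.index.name = "epoch_id"
    frame.insert(0, "label", [e.label for e in epoch_list])
    return frame
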