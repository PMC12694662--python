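"""Plain-text persistence for recordings, epochs and results.

A continuous recording is one CSV file (``time_s``, one column per
channel in µV, and a 0/1 ``trigger`` impulse column marking cue samples)
plus a JSON metadata sidecar carrying the participant, session day,
condition group, movement type, sampling rate, true onsets and idle
intervals.  Epoch sets are stored as long-format CSV
(epoch_id, label, channel, sample_index, value_uv) plus a rejection-log
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .preprocess import Epoch, EpochSet
from .simulate import ContinuousRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "write_epochs",
    "read_epochs",
    "write_onsets",
    "read_onsets",
]


def write_recording(recording: ContinuousRecording, directory: str | Path) -> Path:
    """Write one recording as ``<id>.csv`` + ``<id>.json``; returns the
    CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = recording.recording_id
    n = recording.n_samples
    trigger = np.zeros(n, dtype=int)
    trigger[recording.cue_events] = 1
    frame = pd.DataFrame(
        {"time_s": np.arange(n) / recording.sampling_rate}
        | {label: recording.signal[i] for i, label in enumerate(recording.channel_labels)}
        | {"trigger": trigger}
    )
    csv_path = directory / f"{stem}.csv"
    frame.to_csv(csv_path, index=False, float_format="%.5f")
    sidecar = {
        "participant_id": recording.participant_id,
        "session_day": recording.session_day,
        "group": recording.group,
        "movement_type": recording.movement_type,
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "true_onsets": recording.true_onsets.tolist(),
        "idle_intervals": [list(span) for span in recording.idle_intervals],
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(csv_path: str | Path) -> ContinuousRecording:
    """Read a recording written by ``write_recording`` (or any conforming
    export with the same column layout and sidecar)."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(csv_path)
    labels = meta["channel_labels"]
    missing = [c for c in labels + ["time_s", "trigger"] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{csv_path} lacks columns {missing}")
    signal = frame[labels].to_numpy().T
    cues = np.flatnonzero(frame["trigger"].to_numpy() > 0)
    return ContinuousRecording(
        channel_labels=tuple(labels),
        sampling_rate=float(meta["sampling_rate"]),
        signal=signal,
        cue_events=cues,
        true_onsets=np.asarray(meta.get("true_onsets", []), dtype=int),
        idle_intervals=[tuple(span) for span in meta.get("idle_intervals", [])],
        participant_id=meta["participant_id"],
        session_day=int(meta["session_day"]),
        group=meta["group"],
        movement_type=meta["movement_type"],
    )


def write_cohort(recordings: Sequence[ContinuousRecording], directory: str | Path) -> list[Path]:
    return [write_recording(r, directory) for r in recordings]


def read_cohort(directory: str | Path) -> list[ContinuousRecording]:
    paths = sorted(
        p for p in Path(directory).glob("*.csv") if not p.name.endswith(".epochs.csv")
    )
    return [read_recording(p) for p in paths]


def write_epochs(epochs: EpochSet, directory: str | Path, stem: str) -> Path:
    """Long-format epochs CSV plus a JSON rejection/bookkeeping sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for epoch in epochs:
        for c, channel in enumerate(epochs.channel_labels):
            records.append(
                pd.DataFrame(
                    {
                        "epoch_id": epoch.epoch_id,
                        "label": epoch.label,
                        "channel": channel,
                        "sample_index": np.arange(epoch.n_samples),
                        "value_uv": epoch.data[c],
                    }
                )
            )
    frame = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["epoch_id", "label", "channel", "sample_index", "value_uv"])
    )
    csv_path = directory / f"{stem}.epochs.csv"
    frame.to_csv(csv_path, index=False, float_format="%.5f")
    meta = {
        "channel_labels": list(epochs.channel_labels),
        "sampling_rate": epochs.sampling_rate,
        "rejected_count": epochs.rejected_count,
        "balanced": epochs.balanced,
        "epochs": {
            e.epoch_id: {
                "label": e.label,
                "recording_id": e.recording_id,
                "anchor": int(e.anchor),
                "window": list(e.window),
                "participant_id": e.participant_id,
                "session_day": e.session_day,
                "group": e.group,
                "movement_type": e.movement_type,
            }
            for e in epochs
        },
    }
    (directory / f"{stem}.epochs.json").write_text(json.dumps(meta, indent=1))
    return csv_path


def read_epochs(csv_path: str | Path) -> EpochSet:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")  # <stem>.epochs.csv -> <stem>.epochs.json
    if not sidecar.exists():
        raise SchemaError(f"missing epochs sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    labels = meta["channel_labels"]
    frame = pd.read_csv(csv_path)
    epochs = []
    for epoch_id, info in meta["epochs"].items():
        chunk = frame[frame["epoch_id"] == epoch_id]
        data = np.stack(
            [
                chunk[chunk["channel"] == channel].sort_values("sample_index")["value_uv"].to_numpy()
                for channel in labels
            ]
        )
        epochs.append(
            Epoch(
                epoch_id=epoch_id,
                label=info["label"],
                data=data,
                recording_id=info["recording_id"],
                anchor=info["anchor"],
                window=tuple(info["window"]),
                participant_id=info["participant_id"],
                session_day=info["session_day"],
                group=info["group"],
                movement_type=info["movement_type"],
            )
        )
    return EpochSet(
        epochs=epochs,
        channel_labels=tuple(labels),
        sampling_rate=float(meta["sampling_rate"]),
        rejected_count={k: int(v) for k, v in meta["rejected_count"].items()},
        balanced=bool(meta["balanced"]),
    )


def write_onsets(onsets: dict[str, Sequence[int]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps({k: [int(v) for v in values] for k, values in onsets.items()}, indent=1)
    )
    return path


def read_onsets(path: str | Path) -> dict[str, np.ndarray]:
    data = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=int) for k, v in data.items()}
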