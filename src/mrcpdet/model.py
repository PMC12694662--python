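"""Model-style front-end over the calibration-scenario pipeline.

``MovementIntentionStudy`` is built from a cohort of continuous
recordings (or already-prepared session epochs); ``fit`` evaluates one
calibration scenario and returns a ``CalibrationResults`` object holding
the per-session accuracies, confusion rates, a leakage audit trail and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (
    FEATURE_FAMILIES,
    ScenarioRun,
    ScenarioSpec,
    SessionEpochs,
    run_scenario,
)
from .errors import GroupingError
from .pipeline import prepare_cohort
from .report import chance_level, results_table
from .simulate import ContinuousRecording


class MovementIntentionStudy:
    """Single-trial movement-intention detection study.

    Parameters
    ----------
    cohort
        Prepared ``SessionEpochs`` (see ``from_recordings`` to start from
        continuous signals instead).
    """

    def __init__(self, cohort: Sequence[SessionEpochs]):
        if not cohort:
            raise GroupingError("study needs a non-empty cohort")
        self.cohort = list(cohort)

    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence[ContinuousRecording],
        onset_source: str = "true",
        **prepare_kwargs,
    ) -> "MovementIntentionStudy":
        """Build a study from continuous recordings, running the standard
        preprocessing (0.1-30 Hz zero-phase band-pass, [-2, 0) s movement
        epochs, 150 µV rejection, class balancing)."""
        return cls(prepare_cohort(recordings, onset_source=onset_source, **prepare_kwargs))

    def fit(
        self,
        scenario: str = "within_session",
        feature_families: Sequence[str] = FEATURE_FAMILIES,
        n_trees: int = 128,
        seed: int = 0,
    ) -> "CalibrationResults":
        """Evaluate one calibration scenario on the cohort."""
        spec = ScenarioSpec(
            scenario=scenario,
            feature_families=tuple(feature_families),
            n_trees=n_trees,
            seed=seed,
        )
        run = run_scenario(self.cohort, spec)
        return CalibrationResults(study=self, run=run)


@dataclass
class CalibrationResults:
    """Per-session detection performance for one calibration scenario."""

    study: MovementIntentionStudy
    run: ScenarioRun

    @property
    def results(self):
        return self.run.results

    @property
    def scenario(self) -> str:
        return self.run.spec.scenario

    @property
    def accuracies(self) -> np.ndarray:
        """Per-cell accuracies (%) in result order."""
        return self.run.accuracies()

    @property
    def mean_accuracy(self) -> float:
        return self.run.mean_accuracy

    def table(self) -> pd.DataFrame:
        """Flat unrounded per-cell export (accuracy and confusion rates)."""
        return results_table(self.run.results)

    def chance_levels(self, alpha: float = 0.05) -> pd.DataFrame:
        """Exact binomial chance-level threshold per result cell."""
        rows = []
        for r in self.run.results:
            n = r.rates.n_pos + r.rates.n_neg
            threshold, attainable = chance_level(n, alpha=alpha)
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "session_day": r.session_day,
                    "movement_type": r.movement_type,
                    "n_trials": n,
                    "chance_level_pct": threshold,
                    "attainable": attainable,
                    "accuracy_pct": r.accuracy,
                    "above_chance": attainable and r.accuracy > threshold,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of the scenario evaluation."""
        frame = self.table()
        lines = [
            f"Movement-intention detection — scenario: {self.scenario}",
            f"feature families: {', '.join(self.run.spec.feature_families)}; "
            f"forest size: {self.run.spec.n_trees} trees; seed: {self.run.spec.seed}",
            f"cells evaluated: {len(frame)}; fold errors: {len(self.run.fold_errors)}",
            "",
        ]
        if not frame.empty:
            grouped = (
                frame.groupby(["group", "movement_type"])["accuracy_pct"]
                .agg(["mean", "std", "count"])
                .rename(columns={"mean": "acc_mean_pct", "std": "acc_sd_pct", "count": "n_cells"})
            )
            lines.append(grouped.round(1).to_string())
            lines.append("")
            lines.append(
                frame[
                    [
                        "participant_id",
                        "session_day",
                        "movement_type",
                        "accuracy_pct",
                        "tpr_pct",
                        "tnr_pct",
                    ]
                ]
                .round(1)
                .to_string(index=False)
            )
        return "\n".join(lines)
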