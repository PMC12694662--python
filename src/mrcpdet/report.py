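"""Evaluation metrics, chance levels, grand averages and result tables.

Movement intention is the positive class throughout.  Confusion rates are
expressed in percent: the true-positive and false-negative rates sum to
100, as do the false-positive and true-negative rates.  The chance level
is the smallest accuracy that a random classifier exceeds with
probability below alpha under an exact binomial model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MetricError, ShapeError
from .preprocess import IDLE_LABEL, MOVEMENT_LABEL

__all__ = [
    "ConfusionRates",
    "ScenarioResult",
    "confusion_rates",
    "chance_level",
    "grand_average",
    "results_table",
    "render_tables",
    "round_half_away",
]


@dataclass(frozen=True)
class ConfusionRates:
    """Binary confusion rates in percent, with class counts."""

    tpr: float
    fnr: float
    fpr: float
    tnr: float
    n_pos: int
    n_neg: int

    @property
    def accuracy(self) -> float:
        """Overall accuracy (%) implied by the rates and class counts."""
        total = self.n_pos + self.n_neg
        return (self.tpr * self.n_pos + self.tnr * self.n_neg) / total


@dataclass(frozen=True)
class ScenarioResult:
    """Accuracy and confusion rates of one evaluation cell: one
    participant, session day and movement type under one scenario."""

    scenario: str
    participant_id: str
    session_day: int
    movement_type: str
    group: str
    rates: ConfusionRates

    @property
    def accuracy(self) -> float:
        return self.rates.accuracy


def confusion_rates(
    predictions: Sequence[str], labels: Sequence[str]
) -> ConfusionRates:
    """Rates in percent with ``movement_intention`` as the positive class."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise MetricError(
            f"predictions and labels must be equally long and non-empty, "
            f"got {predictions.shape} vs {labels.shape}"
        )
    pos = labels == MOVEMENT_LABEL
    neg = labels == IDLE_LABEL
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError(
            f"both classes must be present to define the rates "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    tp = int(np.sum(pos & (predictions == MOVEMENT_LABEL)))
    tn = int(np.sum(neg & (predictions == IDLE_LABEL)))
    return ConfusionRates(
        tpr=100.0 * tp / n_pos,
        fnr=100.0 * (n_pos - tp) / n_pos,
        fpr=100.0 * (n_neg - tn) / n_neg,
        tnr=100.0 * tn / n_neg,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def chance_level(
    n_trials: int, alpha: float = 0.05, p0: float = 0.5
) -> tuple[float, bool]:
    """Exact binomial chance-level threshold.

    Returns ``(threshold_pct, attainable)``: the smallest accuracy
    ``100 k / n`` whose right tail probability under Binomial(n, p0) is
    below ``alpha``.  When even a perfect score is not significant (tiny
    n), the threshold is reported as 100% with ``attainable=False``.
    """
    if n_trials < 1:
        raise MetricError(f"n_trials must be >= 1, got {n_trials!r}")
    if not 0 < alpha < 1:
        raise MetricError(f"alpha must lie in (0, 1), got {alpha!r}")
    k = np.arange(n_trials + 1)
    # P(X >= k) for each k
    tail = stats.binom.sf(k - 1, n_trials, p0)
    significant = np.flatnonzero(tail < alpha)
    if significant.size == 0:
        return 100.0, False
    return 100.0 * significant[0] / n_trials, True


def grand_average(
    epoch_sets: Mapping[str, Sequence[np.ndarray]] | Sequence[Sequence[np.ndarray]],
    channel: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-level grand average of epoch waveforms across participants.

    ``epoch_sets`` maps participant -> iterable of (channels x samples)
    epoch arrays.  The per-participant mean waveform is computed first;
    the grand average and the standard error are then taken across the
    participant means (SE = SD of participant means / sqrt(P)).
    Returns ``(mean, standard_error)`` for the requested channel.
    """
    if isinstance(epoch_sets, Mapping):
        groups = list(epoch_sets.values())
    else:
        groups = list(epoch_sets)
    if len(groups) < 2:
        raise MetricError("grand_average needs epochs from at least 2 participants")
    participant_means = []
    for epochs in groups:
        arrays = [np.asarray(e, dtype=float) for e in epochs]
        if not arrays:
            raise MetricError("a participant contributed zero epochs")
        stack = np.stack(arrays)
        participant_means.append(stack.mean(axis=0)[channel])
    lengths = {m.size for m in participant_means}
    if len(lengths) != 1:
        raise ShapeError(f"participants have mismatched epoch lengths: {sorted(lengths)}")
    means = np.stack(participant_means)
    grand = means.mean(axis=0)
    se = means.std(axis=0, ddof=1) / np.sqrt(means.shape[0])
    return grand, se


def plot_grand_average(
    mean: np.ndarray,
    se: np.ndarray,
    sampling_rate: float,
    path: str,
    window: tuple[float, float] = (-2.0, 0.0),
    label: str = "movement intention",
) -> None:
    """Save a grand-average waveform plot with a ±SE band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = window[0] + np.arange(mean.size) / sampling_rate
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(t, mean, lw=1.2, label=label)
    ax.fill_between(t, mean - se, mean + se, alpha=0.3, lw=0)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time relative to movement onset (s)")
    ax.set_ylabel("amplitude (µV)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def round_half_away(x: float) -> int:
    """Round half away from zero (display convention for the tables)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def results_table(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Flat unrounded export of scenario results (one row per cell)."""
    rows = [
        {
            "scenario": r.scenario,
            "group": r.group,
            "participant_id": r.participant_id,
            "session_day": r.session_day,
            "movement_type": r.movement_type,
            "accuracy_pct": r.accuracy,
            "tpr_pct": r.rates.tpr,
            "fnr_pct": r.rates.fnr,
            "fpr_pct": r.rates.fpr,
            "tnr_pct": r.rates.tnr,
            "n_pos": r.rates.n_pos,
            "n_neg": r.rates.n_neg,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _rounded_pair(a: float, b: float) -> tuple[int, int]:
    """Round two complementary percentages so they still sum to 100."""
    ra = round_half_away(a)
    return ra, 100 - ra


def render_tables(results: Iterable[ScenarioResult]) -> dict[str, pd.DataFrame]:
    """Integer-rounded 2x2 confusion tables per scenario cell.

    Keys are ``scenario/group/movement/day``; each value is a 2x2 table
    with true labels on the rows and predicted labels on the columns,
    rows adjusted to sum to 100 after rounding.  Use ``results_table``
    for the unrounded machine-readable export.
    """
    results = list(results)
    if not results:
        raise MetricError("render_tables needs at least one scenario result")
    frame = results_table(results)
    tables: dict[str, pd.DataFrame] = {}
    grouped = frame.groupby(["scenario", "group", "movement_type", "session_day"], sort=True)
    for (scenario, group, movement, day), cell in grouped:
        tpr = cell["tpr_pct"].mean()
        fnr = cell["fnr_pct"].mean()
        fpr = cell["fpr_pct"].mean()
        tnr = cell["tnr_pct"].mean()
        r_tpr, r_fnr = _rounded_pair(tpr, fnr)
        r_fpr, r_tnr = _rounded_pair(fpr, tnr)
        table = pd.DataFrame(
            [[r_tpr, r_fnr], [r_fpr, r_tnr]],
            index=pd.Index([MOVEMENT_LABEL, IDLE_LABEL], name="true"),
            columns=pd.Index([MOVEMENT_LABEL, IDLE_LABEL], name="predicted"),
        )
        tables[f"{scenario}/{group}/{movement}/day{day}"] = table
    return tables
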