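"""Random-forest classification under four calibration scenarios.

The classifier (a 128-tree random forest by default) discriminates
movement-intention from idle epochs.  Four calibration scenarios differ
in where the training data comes from:

* within_session — leave-one-sample-out cross-validation inside one
  session of one participant;
* between_session — train on a participant's other sessions, test on the
  held-out session (every session tested once);
* across_participant — leave-one-participant-out within one condition
  group, scored per held-out session;
* across_condition — train on the full able-bodied cohort, test on the
  cerebral-palsy cohort, scored per participant, day and movement type.

The movement-intention template is refitted inside every fold from the
fold's training epochs only; each fold's template fingerprint is kept so
the absence of train/test leakage is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import (
    FoldError,
    GroupingError,
    InsufficientDataError,
    SchemaError,
)
from .features import (
    FEATURE_FAMILIES,
    Template,
    build_template,
    feature_columns,
    spectral_features,
    template_feature,
    temporal_features,
)
from .preprocess import Epoch, EpochSet, IDLE_LABEL, MOVEMENT_LABEL
from .report import ConfusionRates, ScenarioResult, confusion_rates

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "Fold",
    "FoldPlan",
    "SessionEpochs",
    "plan_within_session",
    "plan_between_session",
    "plan_across_participant",
    "plan_across_condition",
    "run_fold",
    "run_scenario",
    "ScenarioRun",
]

logger = logging.getLogger(__name__)

SCENARIOS = (
    "within_session",
    "between_session",
    "across_participant",
    "across_condition",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """What to run: scenario, feature families, forest size, seed."""

    scenario: str = "within_session"
    feature_families: tuple[str, ...] = FEATURE_FAMILIES
    n_trees: int = 128
    seed: int = 0
    max_features: str | int | float = "sqrt"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SchemaError(f"unknown scenario {self.scenario!r}; allowed: {SCENARIOS}")
        if not self.feature_families:
            raise SchemaError("feature_families must not be empty")
        for fam in self.feature_families:
            if fam not in FEATURE_FAMILIES:
                raise SchemaError(f"unknown feature family {fam!r}")
        if self.n_trees < 1:
            raise SchemaError(f"n_trees must be >= 1, got {self.n_trees!r}")


@dataclass(frozen=True)
class Fold:
    """One train/test split over epoch ids, with provenance tags."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    tags: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise SchemaError("fold train and test sets overlap")


@dataclass(frozen=True)
class FoldPlan:
    """A set of folds; every test epoch appears in exactly one fold."""

    scenario: str
    folds: tuple[Fold, ...]
    tags: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fold in self.folds:
            for epoch_id in fold.test_ids:
                if epoch_id in seen:
                    raise SchemaError(f"epoch {epoch_id} tested in more than one fold")
                seen.add(epoch_id)


@dataclass
class SessionEpochs:
    """The balanced epochs of one (participant, day, movement) session."""

    participant_id: str
    session_day: int
    movement_type: str
    group: str
    epochs: EpochSet

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.participant_id, self.session_day, self.movement_type)


def plan_within_session(session: EpochSet) -> FoldPlan:
    """Leave-one-sample-out: fold i tests epoch i, trains on the rest."""
    ids = session.ids
    if len(ids) < 4:
        raise InsufficientDataError(
            f"within-session cross-validation needs >= 4 epochs, got {len(ids)}"
        )
    folds = tuple(
        Fold(
            train_ids=tuple(ids[:i] + ids[i + 1 :]),
            test_ids=(ids[i],),
            tags={"fold": i},
        )
        for i in range(len(ids))
    )
    return FoldPlan(scenario="within_session", folds=folds)


def plan_between_session(sessions: Sequence[SessionEpochs]) -> list[FoldPlan]:
    """One plan per held-out session: train on the participant's other
    sessions, test on the held-out one.  A participant with a single
    session yields no plans (logged, mirroring the study's exclusion)."""
    if len(sessions) < 2:
        who = sessions[0].participant_id if sessions else "<nobody>"
        logger.info(
            "between-session: participant %s has %d session(s); skipped",
            who,
            len(sessions),
        )
        return []
    plans = []
    for held_out in sessions:
        train_ids: list[str] = []
        for other in sessions:
            if other is not held_out:
                train_ids.extend(other.epochs.ids)
        fold = Fold(
            train_ids=tuple(train_ids),
            test_ids=tuple(held_out.epochs.ids),
            tags={
                "participant_id": held_out.participant_id,
                "session_day": held_out.session_day,
                "movement_type": held_out.movement_type,
                "group": held_out.group,
            },
        )
        plans.append(
            FoldPlan(
                scenario="between_session",
                folds=(fold,),
                tags={"test_day": held_out.session_day},
            )
        )
    return plans


def plan_across_participant(cohort: Sequence[SessionEpochs]) -> list[FoldPlan]:
    """Leave-one-participant-out within a single condition group: one plan
    per participant, whose folds score each held-out session separately
    against a classifier trained on all other participants' sessions."""
    participants = sorted({s.participant_id for s in cohort})
    if len(participants) < 2:
        raise GroupingError(
            f"across-participant needs >= 2 participants, got {len(participants)}"
        )
    groups = {s.group for s in cohort}
    if len(groups) > 1:
        raise GroupingError(
            f"across-participant cohorts must not mix condition groups: {sorted(groups)}"
        )
    plans = []
    for held_out in participants:
        train_ids: list[str] = []
        for s in cohort:
            if s.participant_id != held_out:
                train_ids.extend(s.epochs.ids)
        folds = tuple(
            Fold(
                train_ids=tuple(train_ids),
                test_ids=tuple(s.epochs.ids),
                tags={
                    "participant_id": s.participant_id,
                    "session_day": s.session_day,
                    "movement_type": s.movement_type,
                    "group": s.group,
                },
            )
            for s in cohort
            if s.participant_id == held_out
        )
        plans.append(
            FoldPlan(
                scenario="across_participant",
                folds=folds,
                tags={"held_out": held_out},
            )
        )
    return plans


def plan_across_condition(
    ab_cohort: Sequence[SessionEpochs], cp_cohort: Sequence[SessionEpochs]
) -> FoldPlan:
    """Train on every able-bodied session; score each CP participant,
    day and movement type separately."""
    if not ab_cohort or not cp_cohort:
        raise GroupingError("across-condition needs a non-empty cohort on both sides")
    if any(s.group != "able_bodied" for s in ab_cohort):
        raise GroupingError("training cohort must be able_bodied only")
    if any(s.group != "CP" for s in cp_cohort):
        raise GroupingError("test cohort must be CP only")
    train_ids: list[str] = []
    for s in ab_cohort:
        train_ids.extend(s.epochs.ids)
    folds = tuple(
        Fold(
            train_ids=tuple(train_ids),
            test_ids=tuple(s.epochs.ids),
            tags={
                "participant_id": s.participant_id,
                "session_day": s.session_day,
                "movement_type": s.movement_type,
                "group": s.group,
            },
        )
        for s in cp_cohort
    )
    return FoldPlan(scenario="across_condition", folds=folds)


class _FeatureCache:
    """Per-epoch cache of the fold-independent feature families.

    Temporal and spectral features depend only on the epoch, so they are
    computed once per scenario run; only the template feature changes
    between folds.
    """

    def __init__(self, channel_labels: Sequence[str], sampling_rate: float,
                 families: Sequence[str]):
        self.channel_labels = tuple(channel_labels)
        self.sampling_rate = float(sampling_rate)
        self.families = tuple(families)
        self._base: dict[str, np.ndarray] = {}
        self.columns = feature_columns(self.channel_labels, self.families)

    def _base_vector(self, epoch: Epoch) -> np.ndarray:
        cached = self._base.get(epoch.epoch_id)
        if cached is not None:
            return cached
        parts = []
        for c in range(len(self.channel_labels)):
            x = epoch.data[c]
            if "temporal" in self.families:
                parts.append(temporal_features(x, self.sampling_rate))
            if "spectral" in self.families:
                parts.append(spectral_features(x, self.sampling_rate))
        vec = np.hstack(parts) if parts else np.empty(0)
        self._base[epoch.epoch_id] = vec
        return vec

    def matrix(self, epochs: Sequence[Epoch], template: Template | None) -> np.ndarray:
        """Feature matrix in the documented channel-major column order."""
        n_ch = len(self.channel_labels)
        per_ch_base = (5 if "temporal" in self.families else 0) + (
            23 if "spectral" in self.families else 0
        )
        with_template = "template" in self.families
        if with_template and template is None:
            raise SchemaError("the 'template' family needs a fitted Template")
        n_cols = n_ch * (per_ch_base + (1 if with_template else 0))
        out = np.empty((len(epochs), n_cols))
        for i, epoch in enumerate(epochs):
            base = self._base_vector(epoch)
            col = 0
            for c in range(n_ch):
                seg = base[c * per_ch_base : (c + 1) * per_ch_base]
                out[i, col : col + per_ch_base] = seg
                col += per_ch_base
                if with_template:
                    out[i, col] = template_feature(epoch.data[c], template.data[c])
                    col += 1
        return out


def _fit_forest(
    X: np.ndarray, y: np.ndarray, spec: ScenarioSpec
) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.max_features,
        random_state=spec.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def _predict(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Predict labels; an exactly split ensemble vote goes to idle."""
    idx = list(clf.classes_).index(MOVEMENT_LABEL)
    p_move = clf.predict_proba(X)[:, idx]
    return np.where(p_move > 0.5, MOVEMENT_LABEL, IDLE_LABEL)


@dataclass(frozen=True)
class FoldOutcome:
    """Predictions of one fold plus its leakage-audit trail."""

    test_ids: tuple[str, ...]
    predictions: np.ndarray
    labels: np.ndarray
    template_fingerprint: tuple[str, ...]
    tags: Mapping[str, object]


def run_fold(
    train_epochs: Sequence[Epoch],
    test_epochs: Sequence[Epoch],
    spec: ScenarioSpec,
    channel_labels: Sequence[str],
    sampling_rate: float,
    cache: _FeatureCache | None = None,
) -> FoldOutcome:
    """Train on one fold and predict its test epochs.

    The movement-intention template is fitted on the fold's training
    epochs only, then the restricted feature families are assembled and a
    seeded random forest is fitted.  Deterministic given the spec seed.
    """
    train_labels = {e.label for e in train_epochs}
    if len(train_labels) < 2:
        raise FoldError(
            f"training fold contains a single class {sorted(train_labels)}; skipped"
        )
    if cache is None:
        cache = _FeatureCache(channel_labels, sampling_rate, spec.feature_families)
    template = None
    if "template" in spec.feature_families:
        template = build_template(train_epochs, channel_labels, sampling_rate)
    X_train = cache.matrix(train_epochs, template)
    y_train = np.array([e.label for e in train_epochs])
    X_test = cache.matrix(test_epochs, template)
    clf = _fit_forest(X_train, y_train, spec)
    predictions = _predict(clf, X_test)
    return FoldOutcome(
        test_ids=tuple(e.epoch_id for e in test_epochs),
        predictions=predictions,
        labels=np.array([e.label for e in test_epochs]),
        template_fingerprint=template.fingerprint if template is not None else (),
        tags={},
    )


@dataclass
class ScenarioRun:
    """Everything a scenario produced: per-cell results, the fold audit
    trail, and any fold-level errors (never silently dropped)."""

    spec: ScenarioSpec
    results: list[ScenarioResult]
    outcomes: list[FoldOutcome]
    fold_errors: list[str]

    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.results])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies().mean())


def _group_cells(
    outcomes: Iterable[FoldOutcome],
) -> dict[tuple[str, int, str, str], tuple[list[str], list[str]]]:
    cells: dict[tuple[str, int, str, str], tuple[list[str], list[str]]] = {}
    for outcome in outcomes:
        key = (
            str(outcome.tags.get("participant_id", "")),
            int(outcome.tags.get("session_day", 0)),
            str(outcome.tags.get("movement_type", "")),
            str(outcome.tags.get("group", "")),
        )
        preds, labels = cells.setdefault(key, ([], []))
        preds.extend(outcome.predictions)
        labels.extend(outcome.labels)
    return cells


def run_scenario(cohort: Sequence[SessionEpochs], spec: ScenarioSpec) -> ScenarioRun:
    """Run one calibration scenario over a prepared cohort.

    Returns per (participant, day, movement) accuracies and confusion
    rates.  Fold-level failures (e.g. a single-class training fold) are
    collected in ``fold_errors`` and logged.
    """
    if not cohort:
        raise GroupingError("run_scenario needs a non-empty cohort")
    channel_labels = cohort[0].epochs.channel_labels
    sampling_rate = cohort[0].epochs.sampling_rate
    for s in cohort:
        if s.epochs.channel_labels != channel_labels:
            raise SchemaError("cohort sessions have inconsistent channel sets")
    id_map: dict[str, Epoch] = {}
    for s in cohort:
        for epoch in s.epochs:
            if epoch.epoch_id in id_map:
                raise SchemaError(f"duplicate epoch id {epoch.epoch_id} in cohort")
            id_map[epoch.epoch_id] = epoch

    cache = _FeatureCache(channel_labels, sampling_rate, spec.feature_families)
    outcomes: list[FoldOutcome] = []
    fold_errors: list[str] = []

    def execute(fold: Fold, extra_tags: Mapping[str, object]) -> None:
        try:
            outcome = run_fold(
                [id_map[i] for i in fold.train_ids],
                [id_map[i] for i in fold.test_ids],
                spec,
                channel_labels,
                sampling_rate,
                cache=cache,
            )
        except FoldError as exc:
            message = f"{extra_tags}: {exc}"
            logger.warning("fold skipped: %s", message)
            fold_errors.append(message)
            return
        outcomes.append(
            FoldOutcome(
                test_ids=outcome.test_ids,
                predictions=outcome.predictions,
                labels=outcome.labels,
                template_fingerprint=outcome.template_fingerprint,
                tags={**fold.tags, **extra_tags},
            )
        )

    if spec.scenario == "within_session":
        for s in cohort:
            plan = plan_within_session(s.epochs)
            tags = {
                "participant_id": s.participant_id,
                "session_day": s.session_day,
                "movement_type": s.movement_type,
                "group": s.group,
            }
            for fold in plan.folds:
                execute(fold, tags)
    elif spec.scenario == "between_session":
        by_participant: dict[tuple[str, str], list[SessionEpochs]] = {}
        for s in cohort:
            by_participant.setdefault((s.participant_id, s.movement_type), []).append(s)
        for sessions in by_participant.values():
            sessions.sort(key=lambda s: s.session_day)
            for plan in plan_between_session(sessions):
                for fold in plan.folds:
                    execute(fold, fold.tags)
    elif spec.scenario == "across_participant":
        by_group_movement: dict[tuple[str, str], list[SessionEpochs]] = {}
        for s in cohort:
            by_group_movement.setdefault((s.group, s.movement_type), []).append(s)
        for subcohort in by_group_movement.values():
            for plan in plan_across_participant(subcohort):
                for fold in plan.folds:
                    execute(fold, fold.tags)
    else:  # across_condition
        ab = [s for s in cohort if s.group == "able_bodied"]
        cp = [s for s in cohort if s.group == "CP"]
        plan = plan_across_condition(ab, cp)
        for fold in plan.folds:
            execute(fold, fold.tags)

    results = []
    for (participant, day, movement, group), (preds, labels) in sorted(
        _group_cells(outcomes).items()
    ):
        results.append(
            ScenarioResult(
                scenario=spec.scenario,
                participant_id=participant,
                session_day=day,
                movement_type=movement,
                group=group,
                rates=confusion_rates(preds, labels),
            )
        )
    return ScenarioRun(spec=spec, results=results, outcomes=outcomes, fold_errors=fold_errors)
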