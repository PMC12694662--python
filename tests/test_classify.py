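"""Cross-validation plans, fold execution, leakage safety and the
permutation null."""

import numpy as np
import pytest
from scipy import stats

from mrcpdet import (
    ScenarioSpec,
    SessionEpochs,
    SimulationConfig,
    generate_cohort,
    plan_across_condition,
    plan_across_participant,
    plan_between_session,
    plan_within_session,
    prepare_cohort,
    prepare_session,
    run_fold,
    run_scenario,
)
from mrcpdet.errors import FoldError, GroupingError, InsufficientDataError, SchemaError
from tests.conftest import make_epoch, make_epoch_set

FS = 512.0
N = int(2 * FS)
CHANNELS = ("C3", "C1", "Cz", "C2", "C4")


def toy_session(participant="P00", day=1, movement="wrist", group="able_bodied",
                n_per_class=5, seed=0, separation=5.0):
    rng = np.random.default_rng(seed)
    epochs = []
    for i in range(n_per_class):
        mov = rng.standard_normal((5, N)) - separation
        idl = rng.standard_normal((5, N))
        epochs.append(make_epoch(mov, "movement_intention", f"{participant}-d{day}-{movement}-m{i}"))
        epochs.append(make_epoch(idl, "idle", f"{participant}-d{day}-{movement}-i{i}"))
    return SessionEpochs(
        participant_id=participant,
        session_day=day,
        movement_type=movement,
        group=group,
        epochs=make_epoch_set(epochs),
    )


class TestPlans:
    def test_loso_structure(self):
        session = toy_session(n_per_class=6)
        plan = plan_within_session(session.epochs)
        assert len(plan.folds) == 12
        tested = [fold.test_ids[0] for fold in plan.folds]
        assert sorted(tested) == sorted(session.epochs.ids)
        for fold in plan.folds:
            assert len(fold.train_ids) == 11
            assert set(fold.train_ids) | set(fold.test_ids) == set(session.epochs.ids)

    def test_loso_needs_at_least_four_epochs(self):
        with pytest.raises(InsufficientDataError):
            plan_within_session(toy_session(n_per_class=1).epochs)

    @pytest.mark.parametrize("n_sessions,n_plans", [(3, 3), (2, 2), (1, 0)])
    def test_between_session_combinations(self, n_sessions, n_plans):
        sessions = [toy_session(day=d, seed=d) for d in range(1, n_sessions + 1)]
        plans = plan_between_session(sessions)
        assert len(plans) == n_plans
        for plan, held_out in zip(plans, sessions):
            fold = plan.folds[0]
            assert set(fold.test_ids) == set(held_out.epochs.ids)
            assert not set(fold.train_ids) & set(held_out.epochs.ids)

    def test_across_participant_holds_out_whole_participant(self):
        cohort = [
            toy_session(participant=f"P{i:02d}", day=d, seed=10 * i + d)
            for i in range(3)
            for d in (1, 2)
        ]
        plans = plan_across_participant(cohort)
        assert len(plans) == 3
        for plan in plans:
            held = plan.tags["held_out"]
            for fold in plan.folds:
                assert all(tid.startswith(held) for tid in fold.test_ids)
                assert not any(tid.startswith(held) for tid in fold.train_ids)

    def test_across_participant_rejects_mixed_groups(self):
        cohort = [
            toy_session(participant="P00", group="able_bodied"),
            toy_session(participant="P01", group="CP", seed=1),
        ]
        with pytest.raises(GroupingError):
            plan_across_participant(cohort)

    def test_across_condition_trains_on_able_bodied_only(self):
        ab = [toy_session(participant=f"A{i}", seed=i) for i in range(2)]
        cp = [toy_session(participant="C0", group="CP", seed=9)]
        plan = plan_across_condition(ab, cp)
        train = set(plan.folds[0].train_ids)
        assert train == set(ab[0].epochs.ids) | set(ab[1].epochs.ids)
        with pytest.raises(GroupingError):
            plan_across_condition([], cp)


class TestRunFold:
    def test_separable_classes_classified(self):
        session = toy_session(n_per_class=6, separation=8.0)
        epochs = session.epochs.epochs
        out = run_fold(epochs[2:], epochs[:2], ScenarioSpec(seed=0), CHANNELS, FS)
        np.testing.assert_array_equal(out.predictions, out.labels)

    def test_single_class_training_fold_rejected(self):
        session = toy_session(n_per_class=4)
        movement_only = [e for e in session.epochs if e.label == "movement_intention"]
        with pytest.raises(FoldError):
            run_fold(movement_only, movement_only[:1], ScenarioSpec(seed=0), CHANNELS, FS)

    def test_same_seed_identical_predictions(self):
        session = toy_session(n_per_class=6, separation=0.5)
        epochs = session.epochs.epochs
        a = run_fold(epochs[4:], epochs[:4], ScenarioSpec(seed=3), CHANNELS, FS)
        b = run_fold(epochs[4:], epochs[:4], ScenarioSpec(seed=3), CHANNELS, FS)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_template_fitted_on_training_epochs_only(self):
        session = toy_session(n_per_class=6)
        epochs = session.epochs.epochs
        out = run_fold(epochs[2:], epochs[:2], ScenarioSpec(seed=0), CHANNELS, FS)
        train_ids = {e.epoch_id for e in epochs[2:]}
        assert set(out.template_fingerprint) <= train_ids
        assert not set(out.template_fingerprint) & set(out.test_ids)

    def test_permutation_null_is_at_chance(self):
        # shuffle labels of a separable set; accuracy must fall in the
        # 95% binomial interval around 50%
        rng = np.random.default_rng(12)
        session = toy_session(n_per_class=100, separation=5.0, seed=2)
        epochs = session.epochs.epochs
        labels = [e.label for e in epochs]
        shuffled = rng.permutation(labels)
        permuted = [
            make_epoch(e.data, lbl, e.epoch_id) for e, lbl in zip(epochs, shuffled)
        ]
        train, test = permuted[:100], permuted[100:]
        out = run_fold(train, test, ScenarioSpec(seed=1), CHANNELS, FS)
        correct = int(np.sum(out.predictions == out.labels))
        lo, hi = stats.binom.interval(0.95, len(test), 0.5)
        assert lo <= correct <= hi


class TestRunScenario:
    def test_within_session_single_cell(self, high_snr_session):
        run = run_scenario([high_snr_session], ScenarioSpec("within_session", seed=0))
        assert len(run.results) == 1
        result = run.results[0]
        assert result.rates.n_pos == result.rates.n_neg == 10
        assert run.mean_accuracy >= 95.0

    def test_feature_family_restriction_reaches_classifier(self, high_snr_session):
        run = run_scenario(
            [high_snr_session],
            ScenarioSpec("within_session", feature_families=("spectral",), seed=0),
        )
        assert len(run.results) == 1  # 23 x 5 feature columns used

    def test_across_participant_groups_results_per_session(self):
        cfg = SimulationConfig(
            n_participants=3,
            sessions_per_participant=1,
            trials_per_movement=3,
            idle_block_duration=12.0,
            mrcp_peak_amplitude_mean=10.0,
            noise_std=2.0,
            seed=5,
        )
        cohort = prepare_cohort(generate_cohort(cfg))
        run = run_scenario(cohort, ScenarioSpec("across_participant", seed=0))
        assert len(run.results) == 3
        assert {r.participant_id for r in run.results} == {"AB00", "AB01", "AB02"}

    def test_unknown_scenario_rejected(self):
        with pytest.raises(SchemaError):
            ScenarioSpec("transfer_learning")

    def test_accuracy_nondecreasing_in_amplitude(self):
        # median over seeds of within-session accuracy at 2, 5, 10 µV
        medians = []
        for amp in (2.0, 5.0, 10.0):
            accs = []
            for seed in range(3):
                cfg = SimulationConfig(
                    n_participants=1,
                    sessions_per_participant=1,
                    trials_per_movement=8,
                    idle_block_duration=24.0,
                    mrcp_peak_amplitude_mean=amp,
                    mrcp_amplitude_cv=0.0,
                    session_drift_std=0.0,
                    noise_std=10.0,
                    seed=100 + seed,
                )
                ses = prepare_session(generate_cohort(cfg)[0], balance_seed=seed)
                run = run_scenario([ses], ScenarioSpec("within_session", seed=seed))
                accs.append(run.mean_accuracy)
            medians.append(float(np.median(accs)))
        assert medians[0] <= medians[1] + 1e-9
        assert medians[1] <= medians[2] + 1e-9
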