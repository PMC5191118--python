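"""Experiment harness: leakage guards, subject-wise cross-validation,
activity cases, histograms and baseline comparisons."""

import numpy as np
import pandas as pd
import pytest

from sparsepose.database import MotionDatabase
from sparsepose.estimators import PoseReconstructor, WeightedNeighborPoseRegressor
from sparsepose.evaluation import (
    ActivityCase,
    ExperimentPlan,
    LeakageError,
    activity_case_evaluate,
    assert_no_leakage,
    cross_validate,
    error_histogram,
    evaluate_poses,
    loso_evaluate,
    mean_pose,
    mean_position_error,
)
from tests.conftest import random_unit_quaternions


class TestLeakageGuards:
    def test_overlapping_subjects_rejected(self):
        train = pd.DataFrame({"subject": [1, 2, 3]})
        test = pd.DataFrame({"subject": [3]})
        with pytest.raises(LeakageError):
            assert_no_leakage(train, test)

    def test_disjoint_subjects_accepted(self):
        assert_no_leakage(
            pd.DataFrame({"subject": [1, 2]}), pd.DataFrame({"subject": [3]})
        )

    def test_case_split_never_trains_on_test_subject(self, db_small):
        case = ActivityCase("X", 1, (1, 2, 3))
        from sparsepose.evaluation import _case_split

        train, test = _case_split(db_small, 2, case)
        assert 2 not in set(train.labels["subject"])
        assert set(test.labels["subject"]) == {2}
        assert set(test.labels["trial"]) == {1}

    def test_test_subject_frames_in_training_detected(self, db_small):
        # a deliberately leaky split must be rejected
        leaky_train = db_small.subset_subjects([1, 2])
        test = db_small.subset_subjects([2])
        with pytest.raises(LeakageError):
            assert_no_leakage(leaky_train.labels, test.labels)

    def test_single_subject_database_rejected(self, db_small):
        solo = db_small.subset_subjects([1])
        with pytest.raises(ValueError, match="two subjects"):
            loso_evaluate(solo, ExperimentPlan(test_subject=1))


class TestHistogram:
    def test_all_zero_errors_in_first_bin(self):
        counts, edges = error_histogram(np.zeros(10))
        assert counts.tolist() == [10]
        assert np.allclose(edges, [0.0, 0.03])

    def test_example_bins(self):
        counts, _ = error_histogram([0.01, 0.05, 0.05])
        assert counts.tolist() == [1, 2]

    def test_counts_sum_to_frames(self, rng):
        errs = rng.uniform(0, 0.5, size=321)
        counts, _ = error_histogram(errs)
        assert counts.sum() == 321

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            error_histogram([])


class TestLoso:
    def test_deliberate_leak_with_k1_gives_zero_error(self, db_small, skeleton):
        # copying test-subject poses into the training set and recalling
        # with k=1 must give exactly zero error (the guard works in reverse)
        test = db_small.subset_subjects([3])
        train = db_small  # includes subject 3: deliberate leak
        recon = PoseReconstructor(WeightedNeighborPoseRegressor(n_neighbors=1), "D").fit(train)
        pred = recon.predict(test)
        report = evaluate_poses(test.quaternions, pred, skeleton)
        assert report.mean_position_error == 0.0
        assert report.mean_angle_error == 0.0

    def test_report_bookkeeping_identity(self, db_small, skeleton):
        plan = ExperimentPlan(
            estimator="nns", config="D", test_subject=3, estimator_params={"n_neighbors": 10}
        )
        report = loso_evaluate(db_small, plan, skeleton)
        # overall mean equals mean of per-frame means, and (fixed joint set)
        # the average of per-joint means
        assert np.isclose(report.mean_position_error, report.per_frame_position_error.mean())
        assert np.isclose(
            report.mean_position_error, report.per_joint_position_error.mean()
        )
        assert report.histogram_counts.sum() == report.per_frame_position_error.size

    def test_adjacent_sensor_joint_angle_error_is_zero(self, db_small, skeleton):
        # configuration A measures pelvis and upper legs: the hip joints
        # connect two measured segments, so their angle error vanishes
        plan = ExperimentPlan(
            estimator="nns", config="A", test_subject=3, estimator_params={"n_neighbors": 10}
        )
        report = loso_evaluate(db_small, plan, skeleton)
        for hip in ("RightUpperLeg", "LeftUpperLeg"):
            assert np.allclose(report.per_joint_angle_error.loc[hip], 0.0, atol=1e-9)
        assert report.per_joint_position_error.loc["RightUpperLeg"] < 1e-12

    def test_snapshot_property_frame_permutation(self, db_small, skeleton):
        test = db_small.subset_subjects([3])
        train = db_small.subset_subjects([1, 2])
        recon = PoseReconstructor(WeightedNeighborPoseRegressor(n_neighbors=10), "D").fit(train)
        rep = evaluate_poses(test.quaternions, recon.predict(test), skeleton)
        perm = np.random.default_rng(0).permutation(len(test))
        test_p = test.select(perm)
        rep_p = evaluate_poses(test_p.quaternions, recon.predict(test_p), skeleton)
        assert np.allclose(
            rep.per_frame_position_error[perm], rep_p.per_frame_position_error
        )

    def test_both_estimators_beat_constant_mean_pose_baseline(self, db_small, skeleton):
        train = db_small.subset_subjects([1, 2])
        test = db_small.subset_subjects([3])
        baseline = np.broadcast_to(
            mean_pose(train.quaternions), test.quaternions.shape
        )
        base_err = mean_position_error(test.quaternions, baseline, skeleton)
        for plan in (
            ExperimentPlan("nns", "D", 3, estimator_params={"n_neighbors": 25}),
            ExperimentPlan("ann", "D", 3, seed=0,
                           estimator_params={"hidden_layer_sizes": (40, 20), "max_epochs": 300}),
        ):
            rep = loso_evaluate(db_small, plan, skeleton)
            assert rep.mean_position_error < base_err


class TestCrossValidate:
    def test_folds_are_subject_wise_and_deterministic(self, db_small):
        plans = [
            ExperimentPlan("nns", "D", estimator_params={"n_neighbors": k})
            for k in (5, 50)
        ]
        best1, table1 = cross_validate(db_small, plans, n_folds=3)
        best2, table2 = cross_validate(db_small, plans, n_folds=3)
        assert best1.estimator_params == best2.estimator_params
        assert table1.equals(table2)

    def test_too_few_subjects_rejected(self, db_small):
        with pytest.raises(ValueError, match="subject"):
            cross_validate(db_small, [ExperimentPlan("nns", "D")], n_folds=5)

    def test_interior_k_selected_on_noisy_task(self, rng, skeleton):
        # targets depend smoothly on features, with heavy per-pose noise:
        # k=1 overfits the noise, very large k oversmooths across subjects
        from sparsepose.database import LABEL_COLUMNS
        from sparsepose.skeleton import SEGMENTS
        import sparsepose.quaternions as qt

        n_sub, n_frames = 3, 120
        quats, labels = [], []
        for subj in range(1, n_sub + 1):
            t = np.linspace(0, 4 * np.pi, n_frames) + rng.uniform(0, 2 * np.pi)
            q = np.zeros((n_frames, len(SEGMENTS), 4))
            q[..., 0] = 1.0
            for i, seg in enumerate(SEGMENTS):
                if seg == "Pelvis":
                    continue
                angle = 0.6 * np.sin(t + 0.3 * i) + rng.normal(0, 0.25, n_frames)
                q[:, i, :] = qt.from_axis_angle([0, 1, 0], angle)
            quats.append(q)
            labels.append(
                pd.DataFrame(
                    {"subject": subj, "trial": 1, "activity": "adl",
                     "frame": np.arange(n_frames)}
                )
            )
        db = MotionDatabase(
            np.concatenate(quats), pd.concat(labels, ignore_index=True)[list(LABEL_COLUMNS)],
            SEGMENTS, rate=24.0, referenced=True,
        )
        ks = (1, 20, 239)
        plans = [
            ExperimentPlan("nns", "D", estimator_params={"n_neighbors": k}) for k in ks
        ]
        best, table = cross_validate(db, plans, n_folds=3, skeleton=skeleton)
        errs = table["mean_validation_error_m"].to_numpy()
        assert best.estimator_params["n_neighbors"] == 20
        assert errs[1] < errs[0] and errs[1] < errs[2]


class TestActivityCases:
    def test_excluded_trial_training_set_is_smaller(self, db_small):
        from sparsepose.evaluation import _case_split

        all_trials = ActivityCase("all", 1, (1, 2, 3))
        excl = ActivityCase("excl", 1, (2, 3))
        train_all, _ = _case_split(db_small, 1, all_trials)
        train_excl, _ = _case_split(db_small, 1, excl)
        assert len(train_excl) < len(train_all)

    def test_case_evaluation_reports_between_subject_sd(self, db_small):
        case = ActivityCase("A", 1, (1, 2, 3))
        plans = [ExperimentPlan("nns", "D", estimator_params={"n_neighbors": 10})]
        out = activity_case_evaluate(db_small, case, plans)
        res = out["nns"]
        assert len(res["per_subject_position_error_m"]) == len(db_small.subjects)
        assert np.isclose(
            res["mean_position_error_m"], np.mean(res["per_subject_position_error_m"])
        )
        assert res["sd_position_error_m"] >= 0
        assert "mean_flexion_error_deg" in res
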