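"""Experiment harness: leave-one-subject-out testing, subject-wise
cross-validation, activity-case evaluation and error summarization.

Evaluation is strictly subject-wise: data from the test subject never
appears in training or validation folds (a :class:`LeakageError` is raised
otherwise).  Poses are estimated snapshot-wise — each frame independently —
so per-frame errors are order-independent.

Error metrics (computed via forward kinematics on the skeleton):

* joint position error — Euclidean distance (m) between measured and
  estimated joint positions, pelvis-relative;
* joint angle error — absolute wrapped difference (deg) of the three-way
  Euler decomposition of the relative orientation of adjacent segments.

Summaries average per frame over the reported joint set (all non-root
joints minus an optional exclusion list), then over frames; with a fixed
joint set this equals the average of per-joint means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quaternions as qt
from .database import MotionDatabase, get_configuration
from .estimators import (
    NeuralPoseRegressor,
    PoseReconstructor,
    WeightedNeighborPoseRegressor,
)
from .skeleton import Skeleton, joint_angle_error, joint_position_error

__all__ = [
    "LeakageError",
    "ActivityCase",
    "ExperimentPlan",
    "ErrorReport",
    "assert_no_leakage",
    "error_histogram",
    "mean_pose",
    "mean_position_error",
    "evaluate_poses",
    "loso_evaluate",
    "cross_validate",
    "activity_case_evaluate",
    "TESTING_CASES",
]


class LeakageError(ValueError):
    """Test-subject data found in a training set."""


@dataclass(frozen=True)
class ActivityCase:
    """A testing case: one test trial, a list of training trials.

    The training-trial list applies to the *non-test* subjects only; the
    test trial is taken from the test subject.  Trial ids may legitimately
    appear in both lists because they belong to different subjects —
    leakage is guarded at the (subject, trial) level when the split is
    built.
    """

    name: str
    test_trial: object
    training_trials: tuple

    def __post_init__(self):
        object.__setattr__(self, "training_trials", tuple(self.training_trials))


#: Six testing cases: per activity class, one case whose test trial is in
#: the training list (of other subjects) and one whose test trial is
#: excluded from training everywhere, probing extrapolation to unseen
#: trials.  Trials 1–3 gait, 4–9 sport, 10–16 ADL.
TESTING_CASES = {
    "A": ActivityCase("A", 1, (1, 3, 4, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16)),
    "B": ActivityCase("B", 2, (1, 3, 4, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16)),
    "C": ActivityCase("C", 12, (1, 3, 4, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16)),
    "D": ActivityCase("D", 11, (1, 3, 4, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16)),
    "E": ActivityCase("E", 4, (1, 3, 4, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16)),
    "F": ActivityCase("F", 5, (1, 3, 4, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16)),
}


@dataclass
class ExperimentPlan:
    """What to run: estimator kind, sensor configuration, held-out subject,
    optional activity case and noise spec, and the seed."""

    estimator: str = "nns"
    config: object = "D"
    test_subject: object = None
    activity_case: ActivityCase | None = None
    noise: object = None
    seed: int | None = 0
    estimator_params: dict = field(default_factory=dict)

    def make_estimator(self):
        if self.estimator == "nns":
            return WeightedNeighborPoseRegressor(**self.estimator_params)
        if self.estimator == "ann":
            params = dict(self.estimator_params)
            params.setdefault("random_state", self.seed)
            return NeuralPoseRegressor(**params)
        raise ValueError(f"unknown estimator kind {self.estimator!r}")


@dataclass
class ErrorReport:
    """Per-joint and overall error summary for one evaluation."""

    joints: tuple
    per_joint_position_error: pd.Series
    per_joint_angle_error: pd.DataFrame
    per_frame_position_error: np.ndarray
    per_frame_angle_error: np.ndarray
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray

    @property
    def mean_position_error(self) -> float:
        return float(self.per_frame_position_error.mean())

    @property
    def mean_angle_error(self) -> float:
        return float(self.per_frame_angle_error.mean())

    def summary(self) -> dict:
        return {
            "mean_position_error_m": self.mean_position_error,
            "mean_angle_error_deg": self.mean_angle_error,
            "n_frames": int(self.per_frame_position_error.size),
            "n_joints": len(self.joints),
        }

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def per_joint_table(self) -> pd.DataFrame:
        t = self.per_joint_angle_error.copy()
        t.insert(0, "position_error_m", self.per_joint_position_error)
        return t


def assert_no_leakage(train_labels: pd.DataFrame, test_labels: pd.DataFrame) -> None:
    """Raise :class:`LeakageError` if any test subject appears in training."""
    overlap = set(train_labels["subject"]) & set(test_labels["subject"])
    if overlap:
        raise LeakageError(
            f"test subject(s) {sorted(overlap)} present in the training set"
        )


def error_histogram(errors, bin_width: float = 0.03):
    """Left-closed right-open histogram of per-frame errors from 0.

    Default bin width 0.03 m (3 cm).  Counts sum to the number of frames.
    """
    errors = np.asarray(errors, float).ravel()
    if errors.size == 0:
        raise ValueError("error list must be nonempty")
    n_bins = max(1, int(np.floor(errors.max() / bin_width)) + 1)
    edges = bin_width * np.arange(n_bins + 1)
    idx = np.minimum((errors / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts, edges


def mean_pose(quats: np.ndarray) -> np.ndarray:
    """Normalized componentwise mean pose (per-segment, sign-aligned to the
    first sample) — the constant baseline predictor."""
    quats = np.asarray(quats, float)
    aligned = qt.align_signs(quats, quats[:1])
    avg = aligned.mean(axis=0)
    return qt.normalize(avg)


def _joint_sel(skeleton: Skeleton, joints=None, exclude=()):
    if joints is None:
        joints = [s for s in skeleton.segments if skeleton.parent[s] is not None]
    joints = [j for j in joints if j not in set(exclude)]
    return [skeleton.index(j) for j in joints], tuple(joints)


def mean_position_error(measured, estimated, skeleton: Skeleton, joints=None) -> float:
    err = joint_position_error(measured, estimated, skeleton)
    idx, _ = _joint_sel(skeleton, joints)
    return float(err[..., idx].mean())


def evaluate_poses(
    measured: np.ndarray,
    estimated: np.ndarray,
    skeleton: Skeleton,
    exclude_joints=(),
    bin_width: float = 0.03,
) -> ErrorReport:
    """Error report comparing measured and estimated full-body poses."""
    idx, names = _joint_sel(skeleton, exclude=exclude_joints)
    pos = joint_position_error(measured, estimated, skeleton)[..., idx]
    ang = joint_angle_error(measured, estimated, skeleton)[..., idx, :]
    per_frame_pos = pos.mean(axis=-1)
    per_frame_ang = ang.mean(axis=(-1, -2))
    counts, edges = error_histogram(per_frame_pos, bin_width)
    return ErrorReport(
        joints=names,
        per_joint_position_error=pd.Series(pos.mean(axis=0), index=list(names)),
        per_joint_angle_error=pd.DataFrame(
            ang.mean(axis=0),
            index=list(names),
            columns=["flexion_extension", "abduction_adduction", "internal_external"],
        ),
        per_frame_position_error=per_frame_pos,
        per_frame_angle_error=per_frame_ang,
        histogram_counts=counts,
        histogram_edges=edges,
    )


def _case_split(db: MotionDatabase, test_subject, case: ActivityCase | None):
    labels = db.labels
    test_mask = labels["subject"] == test_subject
    train_mask = ~test_mask
    if case is not None:
        test_mask &= labels["trial"].isin([case.test_trial])
        train_mask &= labels["trial"].isin(case.training_trials)
    if not test_mask.any():
        raise ValueError(f"no test frames for subject {test_subject!r}")
    if not train_mask.any():
        raise ValueError("empty training set")
    train = db.select(train_mask.to_numpy())
    test = db.select(test_mask.to_numpy())
    assert_no_leakage(train.labels, test.labels)
    return train, test


def loso_evaluate(
    db: MotionDatabase,
    plan: ExperimentPlan,
    skeleton: Skeleton | None = None,
    exclude_joints=(),
) -> ErrorReport:
    """Leave-one-subject-out evaluation of one plan.

    Trains (or indexes) on every subject except ``plan.test_subject`` and
    evaluates snapshot-wise on the held-out subject.  ``db`` must already be
    the processed (downsampled, pelvis-referenced) movement database.
    """
    if skeleton is None:
        skeleton = Skeleton()
    if len(db.subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    test_subject = plan.test_subject
    if test_subject is None:
        test_subject = db.subjects[0]
    train, test = _case_split(db, test_subject, plan.activity_case)
    recon = PoseReconstructor(plan.make_estimator(), plan.config).fit(train)
    pred = recon.predict(test)
    return evaluate_poses(test.quaternions, pred, skeleton, exclude_joints)


def cross_validate(
    train_db: MotionDatabase,
    plans,
    n_folds: int = 5,
    skeleton: Skeleton | None = None,
):
    """Subject-wise n-fold cross-validation over a parameter grid.

    Folds are whole subjects (requires at least ``n_folds`` training
    subjects; with exactly ``n_folds`` each fold is one subject).  Returns
    ``(best_plan, table)`` where the best plan minimizes the mean validation
    joint position error; deterministic given data and grid.
    """
    if skeleton is None:
        skeleton = Skeleton()
    subjects = train_db.subjects
    if len(subjects) < n_folds:
        raise ValueError(
            f"need at least {n_folds} subjects for {n_folds}-fold subject-wise CV"
        )
    folds = [list(f) for f in np.array_split(np.asarray(subjects, dtype=object), n_folds)]
    rows = []
    for p, plan in enumerate(plans):
        fold_errors = []
        for fold_subjects in folds:
            val = train_db.subset_subjects(fold_subjects)
            fit_subjects = [s for s in subjects if s not in fold_subjects]
            fit = train_db.subset_subjects(fit_subjects)
            assert_no_leakage(fit.labels, val.labels)
            recon = PoseReconstructor(plan.make_estimator(), plan.config).fit(fit)
            pred = recon.predict(val)
            fold_errors.append(
                mean_position_error(val.quaternions, pred, skeleton)
            )
        rows.append(
            {
                "plan": p,
                "params": dict(plan.estimator_params),
                "mean_validation_error_m": float(np.mean(fold_errors)),
            }
        )
    table = pd.DataFrame(rows)
    best = int(table["mean_validation_error_m"].idxmin())
    return list(plans)[best], table


def activity_case_evaluate(
    db: MotionDatabase,
    case: ActivityCase,
    plans,
    skeleton: Skeleton | None = None,
) -> dict:
    """Evaluate a testing case for each plan, across all test subjects.

    For every subject in turn, the training database is built from the
    case's training trials of the *other* subjects and the test set is the
    case's test trial of that subject.  Returns, per plan, a dict with the
    between-subject mean and standard deviation of the mean joint position
    and (flexion/extension) angle errors.
    """
    if skeleton is None:
        skeleton = Skeleton()
    results = {}
    for plan in plans:
        per_subject_pos, per_subject_flex = [], []
        for subject in db.subjects:
            train, test = _case_split(db, subject, case)
            recon = PoseReconstructor(plan.make_estimator(), plan.config).fit(train)
            pred = recon.predict(test)
            rep = evaluate_poses(test.quaternions, pred, skeleton)
            per_subject_pos.append(rep.mean_position_error)
            per_subject_flex.append(
                float(rep.per_joint_angle_error["flexion_extension"].mean())
            )
        results[plan.estimator] = {
            "case": case.name,
            "mean_position_error_m": float(np.mean(per_subject_pos)),
            "sd_position_error_m": float(np.std(per_subject_pos, ddof=1)),
            "mean_flexion_error_deg": float(np.mean(per_subject_flex)),
            "sd_flexion_error_deg": float(np.std(per_subject_flex, ddof=1)),
            "per_subject_position_error_m": per_subject_pos,
        }
    return results
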