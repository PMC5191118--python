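"""Synthetic multi-subject, multi-activity motion generator.

Real six-subject motion-capture recordings are not available, so every
pipeline stage is exercised on generated data with the statistical
structure the estimators assume:

* smooth unit-quaternion trajectories over the 23-segment kinematic tree,
  sampled at a nominal 240 Hz;
* tree consistency — each segment's *local* (relative-to-parent) rotation
  is generated and composed down the tree, so child orientations are
  correlated with their parents;
* a shared low-dimensional latent drive: per activity style, a fixed random
  mixing matrix maps a handful of band-limited latent signals to all local
  joint rotations.  The map is shared across subjects (subjects differ in
  skeleton scale, latent realizations and small per-segment noise), which
  is exactly the learnability premise of the method — similar input
  features imply similar full-body poses, within and across subjects;
* a cyclic gait style whose leg rotations are deterministic sinusoids,
  phase-locked left/right at half a period.

The generator makes no claim of biomechanical realism (no muscle models or
ground contact); it produces smooth, tree-consistent orientation fields
sufficient to test snapshot pose estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from . import quaternions as qt
from .database import LABEL_COLUMNS, MotionDatabase
from .skeleton import SEGMENTS, Skeleton

__all__ = ["MotionGeneratorSpec", "generate_skeletons", "generate_motion", "generate_database"]

STYLES = ("gait", "adl", "sport")

_LEG_SEGMENTS = (
    "RightUpperLeg", "RightLowerLeg", "RightFoot", "RightToe",
    "LeftUpperLeg", "LeftLowerLeg", "LeftFoot", "LeftToe",
)

# per-segment local-rotation amplitude profile (radians): limbs move a lot,
# the spine little
_AMPLITUDE = {s: 0.15 for s in SEGMENTS}
_AMPLITUDE.update(
    {
        "RightUpperArm": 0.5, "LeftUpperArm": 0.5,
        "RightForearm": 0.5, "LeftForearm": 0.5,
        "RightHand": 0.3, "LeftHand": 0.3,
        "RightShoulder": 0.1, "LeftShoulder": 0.1,
        "RightUpperLeg": 0.4, "LeftUpperLeg": 0.4,
        "RightLowerLeg": 0.4, "LeftLowerLeg": 0.4,
        "RightFoot": 0.25, "LeftFoot": 0.25,
        "RightToe": 0.1, "LeftToe": 0.1,
        "Head": 0.1, "Neck": 0.1,
    }
)


@dataclass(frozen=True)
class MotionGeneratorSpec:
    """Study-condition parameters of the generated data set.

    Defaults emulate the source protocol at desk scale: six subjects, three
    trials each (one per activity style), 2500 frames per trial at 240 Hz —
    after the standard factor-10 downsampling this yields 4500 database
    poses.  Subject anthropometry varies with the relative height spread of
    the study population (7.2/177.2 ≈ 4 %).
    """

    n_subjects: int = 6
    trials_per_subject: int = 3
    frames_per_trial: int = 2500
    rate: float = 240.0
    bandwidth_hz: float = 1.0
    latent_dim: int = 4
    subject_scale_sd: float = 7.2 / 177.2
    gait_period_frames: int = 240
    noise_amplitude_rad: float = 0.05
    max_step_deg: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "trials_per_subject", "frames_per_trial", "latent_dim"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bandwidth_hz < 0 or self.bandwidth_hz >= self.rate / 2.0:
            raise ValueError("bandwidth must be nonnegative and below the Nyquist rate")
        if self.gait_period_frames % 2 != 0:
            raise ValueError("gait period must be an even number of frames")

    @property
    def max_step_rad(self) -> float:
        """Per-frame cap on each segment's local rotation increment."""
        return float(np.deg2rad(self.max_step_deg))

    def style_of_trial(self, trial: int) -> str:
        return STYLES[(trial - 1) % len(STYLES)]


def _rng(seed, *keys) -> np.random.Generator:
    import zlib

    # deterministic across processes (no reliance on PYTHONHASHSEED)
    subkeys = [zlib.crc32(repr(k).encode()) for k in keys]
    return np.random.default_rng([int(seed) % (2**31), *subkeys])


def _smooth_signals(rng, n_channels: int, n_frames: int, rate: float, bandwidth: float):
    """Band-limited unit-variance signals, or constants when bandwidth is 0."""
    white = rng.standard_normal((n_channels, n_frames))
    if bandwidth == 0.0 or n_frames < 16:
        return np.repeat(white[:, :1], n_frames, axis=1)
    b, a = sps.butter(2, bandwidth / (rate / 2.0))
    smooth = sps.filtfilt(b, a, white, axis=1)
    sd = smooth.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return smooth / sd


def _limit_steps(rotvec: np.ndarray, max_step: float) -> np.ndarray:
    """Clamp per-frame increments of a rotation-vector series to max_step."""
    out = rotvec.copy()
    for t in range(1, out.shape[0]):
        d = out[t] - out[t - 1]
        n = np.linalg.norm(d)
        if n > max_step:
            out[t] = out[t - 1] + d * (max_step / n)
    return out


def generate_skeletons(spec: MotionGeneratorSpec):
    """Per-subject skeletons: the template scaled by a factor drawn with the
    configured standard deviation (reproducible from the seed)."""
    rng = _rng(spec.seed, "skeletons")
    factors = 1.0 + spec.subject_scale_sd * rng.standard_normal(spec.n_subjects)
    return [Skeleton.template().scaled(float(f)) for f in factors]


def _style_mixing(spec: MotionGeneratorSpec, style: str) -> np.ndarray:
    """Fixed latent→rotation mixing matrix (n_segments, 3, latent_dim),
    shared by every subject performing the style."""
    rng = _rng(spec.seed, "mixing", style)
    M = rng.standard_normal((len(SEGMENTS), 3, spec.latent_dim))
    M /= np.linalg.norm(M, axis=(1, 2), keepdims=True)
    amp = np.array([_AMPLITUDE[s] for s in SEGMENTS])
    gain = {"gait": 0.7, "adl": 1.0, "sport": 1.4}[style]
    M *= gain * amp[:, None, None]
    if style == "gait":
        # legs are driven purely by the deterministic cyclic component
        for s in _LEG_SEGMENTS:
            M[SEGMENTS.index(s)] = 0.0
    return M


def _gait_cycle(spec: MotionGeneratorSpec, rng, n_frames: int) -> dict:
    """Cyclic leg (and arm-swing) rotation vectors.

    Each right-side trajectory is a sinusoidal gait pattern scaled by a slow
    aperiodic envelope (so strides vary and no two frames repeat exactly);
    the left-side trajectory is the *same* series shifted by exactly half a
    period, so left/right symmetry holds bit-exactly.
    """
    period = spec.gait_period_frames
    half = period // 2
    m = n_frames + half
    phase = 2.0 * np.pi * np.arange(m) / period
    env = 1.0 + 0.25 * _smooth_signals(rng, 1, m, spec.rate, 0.2)[0]
    hip_amp = rng.uniform(0.3, 0.6)
    knee_amp = rng.uniform(0.3, 0.7)
    foot_amp = rng.uniform(0.05, 0.2)
    arm_amp = rng.uniform(0.1, 0.4)

    def about_y(theta):
        out = np.zeros((m, 3))
        out[:, 1] = theta
        return out

    patterns = {
        "UpperLeg": about_y(env * hip_amp * np.sin(phase)),
        "LowerLeg": about_y(-env * knee_amp * 0.5 * (1.0 - np.cos(phase))),
        "Foot": about_y(env * foot_amp * np.sin(phase + 0.5)),
        "Toe": about_y(env * 0.3 * foot_amp * np.sin(phase + 1.0)),
        "UpperArm": about_y(env * arm_amp * np.sin(phase + np.pi)),
    }
    out = {}
    for name, series in patterns.items():
        out[f"Right{name}"] = series[:n_frames]
        out[f"Left{name}"] = series[half : half + n_frames]
    return out


def generate_motion(
    spec: MotionGeneratorSpec, subject: int, trial: int, style: str | None = None
) -> np.ndarray:
    """Raw global segment orientations for one trial.

    Returns an array ``(frames_per_trial, 23, 4)`` of scalar-first unit
    quaternions in a laboratory frame (the pelvis carries a slow random
    heading walk, removed later by pelvis referencing).
    """
    if style is None:
        style = spec.style_of_trial(trial)
    n = spec.frames_per_trial
    rng = _rng(spec.seed, "motion", subject, trial)
    skel = Skeleton()

    M = _style_mixing(spec, style)
    z = _smooth_signals(rng, spec.latent_dim, n, spec.rate, spec.bandwidth_hz)
    # latent-driven local rotation vectors (n, 23, 3)
    rotvec = np.einsum("stl,ln->nst", M, z)

    # small independent per-segment noise (never on gait legs, preserving
    # the exact left/right symmetry)
    noise = spec.noise_amplitude_rad * np.moveaxis(
        _smooth_signals(rng, len(SEGMENTS) * 3, n, spec.rate, spec.bandwidth_hz).reshape(
            len(SEGMENTS), 3, n
        ),
        2,
        0,
    )
    if style == "gait":
        for s in _LEG_SEGMENTS:
            noise[:, SEGMENTS.index(s), :] = 0.0
    rotvec = rotvec + noise

    if style == "gait" and spec.bandwidth_hz > 0.0:
        for seg, rv in _gait_cycle(spec, rng, n).items():
            i = SEGMENTS.index(seg)
            if seg in _LEG_SEGMENTS:
                rotvec[:, i, :] = rv
            else:
                rotvec[:, i, :] += rv

    # pelvis: slow heading walk plus slight lean, in the global frame
    pelvis_rv = np.zeros((n, 3))
    heading = np.cumsum(rng.normal(0.0, 0.002, size=n))
    pelvis_rv[:, 2] = heading + rng.uniform(-np.pi, np.pi)
    pelvis_rv[:, :2] = 0.1 * _smooth_signals(rng, 2, n, spec.rate, spec.bandwidth_hz).T
    if spec.bandwidth_hz == 0.0:
        pelvis_rv[:] = pelvis_rv[0]

    # clamp per-frame increments, then build local quaternions
    local = np.empty((n, len(SEGMENTS), 4))
    for i, seg in enumerate(SEGMENTS):
        rv = pelvis_rv if seg == "Pelvis" else _limit_steps(rotvec[:, i, :], spec.max_step_rad)
        r = Rotation.from_rotvec(rv).as_quat()  # scalar-last
        local[:, i, :] = r[:, [3, 0, 1, 2]]

    # compose down the tree: global = parent_global ⊗ local
    glob = np.empty_like(local)
    for seg in skel.topological_order():
        i = skel.index(seg)
        p = skel.parent[seg]
        if p is None:
            glob[:, i, :] = local[:, i, :]
        else:
            glob[:, i, :] = qt.multiply(glob[:, skel.index(p), :], local[:, i, :])
    return qt.normalize(glob)


def generate_database(spec: MotionGeneratorSpec | None = None) -> MotionDatabase:
    """Full raw multi-subject database at the nominal rate (unreferenced)."""
    if spec is None:
        spec = MotionGeneratorSpec()
    quats, labels = [], []
    for subject in range(1, spec.n_subjects + 1):
        for trial in range(1, spec.trials_per_subject + 1):
            style = spec.style_of_trial(trial)
            q = generate_motion(spec, subject, trial, style)
            quats.append(q)
            labels.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "trial": trial,
                        "activity": style,
                        "frame": np.arange(q.shape[0]),
                    }
                )
            )
    return MotionDatabase(
        np.concatenate(quats, axis=0),
        pd.concat(labels, ignore_index=True)[list(LABEL_COLUMNS)],
        SEGMENTS,
        rate=spec.rate,
        referenced=False,
    )
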