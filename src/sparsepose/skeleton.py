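"""Kinematic skeleton, forward kinematics and joint-angle extraction.

The skeleton is a tree of 23 body segments rooted at the pelvis, matching
the segment list of a full-body inertial motion-capture suit (pelvis, a
lumbar/thoracic spine chain, neck, head, shoulders, upper/lower arms, hands,
upper/lower legs, feet and toes).  Each non-root segment stores an *offset*:
the 3-vector (meters) from its parent's joint to its own joint, expressed in
the parent's undisturbed (calibration) frame.

Joint positions follow from forward kinematics starting at the pelvis:

    pos(child) = pos(parent) + R(q_parent) @ offset(child)

with the pelvis joint pinned at the origin.  Because poses are expressed
relative to the pelvis, all positions are pelvis-relative; global position
tracking is out of scope.

Joint angles are the relative orientation of adjacent segments,
``q_rel = q_proximal^-1 ⊗ q_distal``, decomposed into three ordered
rotations (default intrinsic Z–X–Y: flexion/extension, abduction/adduction,
internal/external rotation).

No anthropometric tables are printed by any source this package relies on;
the template offsets below are a synthetic stand-in for a 1.77 m adult and
are expected to be replaced by user-supplied skeleton files for real use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from . import quaternions as qt

__all__ = [
    "SEGMENTS",
    "PARENTS",
    "Skeleton",
    "forward_kinematics",
    "joint_angles",
    "joint_position_error",
    "joint_angle_error",
    "wrap_angle_difference",
    "write_bvh",
]

#: Canonical 23-segment list (root first).
SEGMENTS = (
    "Pelvis",
    "L5",
    "L3",
    "T12",
    "T8",
    "Neck",
    "Head",
    "RightShoulder",
    "RightUpperArm",
    "RightForearm",
    "RightHand",
    "LeftShoulder",
    "LeftUpperArm",
    "LeftForearm",
    "LeftHand",
    "RightUpperLeg",
    "RightLowerLeg",
    "RightFoot",
    "RightToe",
    "LeftUpperLeg",
    "LeftLowerLeg",
    "LeftFoot",
    "LeftToe",
)

PARENTS = {
    "Pelvis": None,
    "L5": "Pelvis",
    "L3": "L5",
    "T12": "L3",
    "T8": "T12",
    "Neck": "T8",
    "Head": "Neck",
    "RightShoulder": "T8",
    "RightUpperArm": "RightShoulder",
    "RightForearm": "RightUpperArm",
    "RightHand": "RightForearm",
    "LeftShoulder": "T8",
    "LeftUpperArm": "LeftShoulder",
    "LeftForearm": "LeftUpperArm",
    "LeftHand": "LeftForearm",
    "RightUpperLeg": "Pelvis",
    "RightLowerLeg": "RightUpperLeg",
    "RightFoot": "RightLowerLeg",
    "RightToe": "RightFoot",
    "LeftUpperLeg": "Pelvis",
    "LeftLowerLeg": "LeftUpperLeg",
    "LeftFoot": "LeftLowerLeg",
    "LeftToe": "LeftFoot",
}

# Synthetic anthropometric template (meters) for a 1.77 m adult.
# Axes: x forward, y left, z up; segment frames aligned with the global
# frame in the neutral calibration posture.
_TEMPLATE_OFFSETS = {
    "L5": (0.0, 0.0, 0.10),
    "L3": (0.0, 0.0, 0.10),
    "T12": (0.0, 0.0, 0.10),
    "T8": (0.0, 0.0, 0.12),
    "Neck": (0.0, 0.0, 0.12),
    "Head": (0.0, 0.0, 0.10),
    "RightShoulder": (0.0, -0.04, 0.10),
    "RightUpperArm": (0.0, -0.15, 0.0),
    "RightForearm": (0.0, 0.0, -0.28),
    "RightHand": (0.0, 0.0, -0.26),
    "LeftShoulder": (0.0, 0.04, 0.10),
    "LeftUpperArm": (0.0, 0.15, 0.0),
    "LeftForearm": (0.0, 0.0, -0.28),
    "LeftHand": (0.0, 0.0, -0.26),
    "RightUpperLeg": (0.0, -0.09, 0.0),
    "RightLowerLeg": (0.0, 0.0, -0.44),
    "RightFoot": (0.0, 0.0, -0.43),
    "RightToe": (0.15, 0.0, -0.05),
    "LeftUpperLeg": (0.0, 0.09, 0.0),
    "LeftLowerLeg": (0.0, 0.0, -0.44),
    "LeftFoot": (0.0, 0.0, -0.43),
    "LeftToe": (0.15, 0.0, -0.05),
}

_TEMPLATE_HEIGHT = 1.77


@dataclass(frozen=True)
class Skeleton:
    """Kinematic tree rooted at the pelvis.

    Parameters
    ----------
    segments : tuple of str
        Ordered segment names; the pose arrays used throughout the package
        follow this order on their segment axis.
    parent : dict
        Maps each segment to its parent name (``None`` for the root).
    offsets : dict
        Maps each non-root segment to its joint offset (3-vector, meters)
        in the parent's undisturbed frame.
    """

    segments: tuple = SEGMENTS
    parent: dict = field(default_factory=lambda: dict(PARENTS))
    offsets: dict = field(
        default_factory=lambda: {k: np.asarray(v, float) for k, v in _TEMPLATE_OFFSETS.items()}
    )

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        roots = [s for s in segs if self.parent.get(s) is None]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {roots}")
        object.__setattr__(
            self, "offsets", {k: np.asarray(v, float) for k, v in self.offsets.items()}
        )
        for s in segs:
            p = self.parent[s]
            if p is None:
                continue
            if p not in segs:
                raise ValueError(f"parent {p!r} of segment {s!r} is not a segment")
            off = self.offsets[s]
            if off.shape != (3,) or not np.all(np.isfinite(off)):
                raise ValueError(f"offset of {s!r} must be a finite 3-vector")
            if np.linalg.norm(off) <= 0.0:
                raise ValueError(f"offset norm of non-root segment {s!r} must be positive")
        # cycle check via walk-to-root
        for s in segs:
            seen = set()
            cur = s
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle detected at segment {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(segs)})

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> str:
        return next(s for s in self.segments if self.parent[s] is None)

    def index(self, segment: str) -> int:
        return self._index[segment]

    def topological_order(self):
        """Segments ordered parents-before-children."""
        order, placed = [], set()
        remaining = list(self.segments)
        while remaining:
            for s in list(remaining):
                p = self.parent[s]
                if p is None or p in placed:
                    order.append(s)
                    placed.add(s)
                    remaining.remove(s)
        return order

    def depth(self, segment: str) -> int:
        d, cur = 0, segment
        while self.parent[cur] is not None:
            cur = self.parent[cur]
            d += 1
        return d

    def children(self, segment: str):
        return [s for s in self.segments if self.parent[s] == segment]

    def scaled(self, factor: float) -> "Skeleton":
        """Uniformly scale all offsets (anthropometric scaling)."""
        return Skeleton(
            self.segments,
            dict(self.parent),
            {k: v * float(factor) for k, v in self.offsets.items()},
        )

    @classmethod
    def template(cls, height: float = _TEMPLATE_HEIGHT) -> "Skeleton":
        """Default 23-segment skeleton scaled to a subject height (m)."""
        return cls().scaled(height / _TEMPLATE_HEIGHT)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": list(self.segments),
            "parent": {k: v for k, v in self.parent.items()},
            "offsets": {k: [float(x) for x in v] for k, v in self.offsets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Skeleton":
        return cls(tuple(d["segments"]), dict(d["parent"]), d["offsets"])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Skeleton":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _check_pose(quats, skeleton: Skeleton, name: str = "pose") -> np.ndarray:
    quats = np.asarray(quats, dtype=float)
    if quats.shape[-2] != len(skeleton.segments) or quats.shape[-1] != 4:
        raise ValueError(
            f"incomplete {name}: expected shape (..., {len(skeleton.segments)}, 4), "
            f"got {quats.shape}"
        )
    if not np.all(np.isfinite(quats)):
        raise ValueError(f"incomplete {name}: non-finite segment orientation")
    return quats


def forward_kinematics(quats, skeleton: Skeleton) -> np.ndarray:
    """Joint positions (meters) from segment orientations.

    Parameters
    ----------
    quats : array, shape (..., n_segments, 4)
        Scalar-first unit quaternions per segment, ordered like
        ``skeleton.segments``, expressed in the pelvis frame.

    Returns
    -------
    positions : array, shape (..., n_segments, 3)
        Joint position per segment; the root joint is at the origin.
    """
    quats = _check_pose(quats, skeleton)
    pos = np.zeros(quats.shape[:-1] + (3,))
    for seg in skeleton.topological_order():
        p = skeleton.parent[seg]
        if p is None:
            continue
        i, j = skeleton.index(seg), skeleton.index(p)
        pos[..., i, :] = pos[..., j, :] + qt.rotate_vector(
            quats[..., j, :], skeleton.offsets[seg]
        )
    return pos


def _euler_from_relative(rel_quats: np.ndarray, order: str, degrees: bool) -> np.ndarray:
    flat = rel_quats.reshape(-1, 4)
    # scipy uses scalar-last component order
    return (
        Rotation.from_quat(flat[:, [1, 2, 3, 0]])
        .as_euler(order, degrees=degrees)
        .reshape(rel_quats.shape[:-1] + (3,))
    )


def joint_angles(
    quats,
    skeleton: Skeleton,
    order: str = "ZXY",
    degrees: bool = True,
    gimbal_atol: float = 1e-6,
) -> np.ndarray:
    """Three-component joint angles at every non-root segment's joint.

    The joint named after a segment is the one connecting it to its parent;
    its angles are the Euler decomposition (intrinsic, default Z–X–Y:
    flexion/extension, abduction/adduction, internal/external rotation) of
    ``q_parent^-1 ⊗ q_segment`` in the proximal frame.  The root row is zero.

    A middle angle within ``gimbal_atol`` degrees of ±90° is flagged with a
    warning (gimbal proximity), not an error.
    """
    quats = _check_pose(quats, skeleton)
    angles = np.zeros(quats.shape[:-1] + (3,))
    for seg in skeleton.segments:
        p = skeleton.parent[seg]
        if p is None:
            continue
        i, j = skeleton.index(seg), skeleton.index(p)
        rel = qt.multiply(qt.inverse(quats[..., j, :]), quats[..., i, :])
        angles[..., i, :] = _euler_from_relative(rel, order, degrees)
    middle = angles[..., 1]
    limit = 90.0 if degrees else np.pi / 2
    if np.any(np.abs(np.abs(middle) - limit) < gimbal_atol):
        warnings.warn("joint angle decomposition near gimbal lock", RuntimeWarning)
    return angles


def joint_position_error(measured, estimated, skeleton: Skeleton) -> np.ndarray:
    """Per-joint Euclidean distance (m) between measured and estimated poses."""
    pm = forward_kinematics(measured, skeleton)
    pe = forward_kinematics(estimated, skeleton)
    return np.linalg.norm(pm - pe, axis=-1)


def wrap_angle_difference(a, b, degrees: bool = True) -> np.ndarray:
    """Absolute angular difference wrapped into [0, 180] degrees."""
    period = 360.0 if degrees else 2.0 * np.pi
    d = np.asarray(a, float) - np.asarray(b, float)
    return np.abs((d + period / 2.0) % period - period / 2.0)


def joint_angle_error(measured, estimated, skeleton: Skeleton, order: str = "ZXY") -> np.ndarray:
    """Componentwise absolute joint-angle difference, wrapped to [0, 180]°."""
    am = joint_angles(measured, skeleton, order=order)
    ae = joint_angles(estimated, skeleton, order=order)
    return wrap_angle_difference(am, ae)


def write_bvh(path, quats, skeleton: Skeleton, frame_time: float = 1.0 / 24.0) -> None:
    """Export a pose sequence as a BVH file (hierarchy + Z–X–Y Euler channels).

    Offsets are written in centimeters (BVH convention is unit-agnostic but
    viewers commonly assume cm).
    """
    quats = np.asarray(quats, float)
    if quats.ndim == 2:
        quats = quats[None]
    quats = _check_pose(quats, skeleton)

    lines = ["HIERARCHY"]
    channel_order: list = []

    def emit(seg: str, indent: int):
        pad = "  " * indent
        channel_order.append(seg)
        if skeleton.parent[seg] is None:
            lines.append(f"{pad}ROOT {seg}")
            off = np.zeros(3)
        else:
            lines.append(f"{pad}JOINT {seg}")
            off = skeleton.offsets[seg] * 100.0
        lines.append(f"{pad}{{")
        lines.append(f"{pad}  OFFSET {off[0]:.4f} {off[1]:.4f} {off[2]:.4f}")
        if skeleton.parent[seg] is None:
            lines.append(
                f"{pad}  CHANNELS 6 Xposition Yposition Zposition "
                "Zrotation Xrotation Yrotation"
            )
        else:
            lines.append(f"{pad}  CHANNELS 3 Zrotation Xrotation Yrotation")
        kids = skeleton.children(seg)
        if not kids:
            lines.append(f"{pad}  End Site")
            lines.append(f"{pad}  {{")
            lines.append(f"{pad}    OFFSET 0.0 0.0 10.0")
            lines.append(f"{pad}  }}")
        for k in kids:
            emit(k, indent + 1)
        lines.append(f"{pad}}}")

    emit(skeleton.root, 0)
    lines.append("MOTION")
    lines.append(f"Frames: {quats.shape[0]}")
    lines.append(f"Frame Time: {frame_time:.6f}")

    for t in range(quats.shape[0]):
        vals = [0.0, 0.0, 0.0]
        for seg in channel_order:
            p = skeleton.parent[seg]
            i = skeleton.index(seg)
            if p is None:
                rel = quats[t, i]
            else:
                rel = qt.multiply(qt.inverse(quats[t, skeleton.index(p)]), quats[t, i])
            vals.extend(_euler_from_relative(rel, "ZXY", True).ravel().tolist())
        lines.append(" ".join(f"{v:.4f}" for v in vals))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
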