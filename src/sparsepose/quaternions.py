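"""Quaternion algebra on scalar-first arrays.

All functions operate on numpy arrays whose last axis has length 4 and holds
the components ``(w, x, y, z)`` — scalar first.  A unit quaternion ``q`` and
its negation ``-q`` encode the same spatial rotation (the double cover of
SO(3)); every distance defined here is invariant under that sign flip.

The central primitive is :func:`shortest_angle`, the per-segment term of the
mean-quaternion-shortest-angle pose distance used by the nearest-neighbor
pose estimator: ``2 * arccos(|[(a)^-1 ⊗ b]_1|)``, where ``[·]_1`` extracts
the scalar component.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "multiply",
    "conjugate",
    "inverse",
    "norm",
    "normalize",
    "rotate_vector",
    "from_axis_angle",
    "shortest_angle",
    "align_signs",
    "sign_continuity",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _as_quat(q, name: str = "quaternion") -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"{name} must have 4 components on the last axis, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError(f"{name} has non-finite components")
    return q


def multiply(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (broadcasts over leading axes)."""
    a = _as_quat(a, "a")
    b = _as_quat(b, "b")
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def conjugate(q) -> np.ndarray:
    q = _as_quat(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def norm(q) -> np.ndarray:
    return np.linalg.norm(_as_quat(q), axis=-1)


def inverse(q) -> np.ndarray:
    """Quaternion inverse; equals the conjugate for unit quaternions."""
    q = _as_quat(q)
    n2 = np.sum(q * q, axis=-1, keepdims=True)
    if np.any(n2 == 0.0):
        raise ValueError("cannot invert a zero-norm quaternion")
    return conjugate(q) / n2


def normalize(q, tol: float = 1e-12) -> np.ndarray:
    """Scale to unit norm, preserving direction.

    Raises
    ------
    ValueError
        If any norm is below ``tol`` (degenerate quaternion).
    """
    q = _as_quat(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < tol):
        raise ValueError("degenerate quaternion: norm below tolerance")
    return q / n


def rotate_vector(q, v) -> np.ndarray:
    """Rotate 3-vectors ``v`` by unit quaternions ``q`` (broadcasts)."""
    q = _as_quat(q)
    v = np.asarray(v, dtype=float)
    w = q[..., 0:1]
    u = q[..., 1:4]
    # v' = v + 2 w (u × v) + 2 u × (u × v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def from_axis_angle(axis, angle_rad) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    angle = np.asarray(angle_rad, dtype=float)[..., None]
    return np.concatenate(
        [np.cos(angle / 2.0), np.sin(angle / 2.0) * axis], axis=-1
    )


def shortest_angle(a, b, absolute: bool = True, unit_atol: float = 1e-6) -> np.ndarray:
    """Shortest rotation angle (radians) between two unit quaternions.

    Computes ``2 * arccos([(a)^-1 ⊗ b]_1)`` with the scalar component taken
    in absolute value by default, so the result lies in ``[0, pi]`` and is
    invariant under a sign flip of either argument.  With
    ``absolute=False`` the raw scalar component is used (range ``[0, 2*pi]``,
    not double-cover invariant); this literal variant exists for comparison
    only.

    The arccos argument is clamped into ``[-1, 1]`` to absorb floating-point
    drift for near-identical orientations.
    """
    a = _as_quat(a, "a")
    b = _as_quat(b, "b")
    for q, name in ((a, "a"), (b, "b")):
        if np.any(np.abs(np.linalg.norm(q, axis=-1) - 1.0) > unit_atol):
            raise ValueError(f"{name} is not a unit quaternion (tolerance {unit_atol})")
    scalar = multiply(inverse(a), b)[..., 0]
    if absolute:
        scalar = np.abs(scalar)
    return 2.0 * np.arccos(np.clip(scalar, -1.0, 1.0))


def align_signs(q, reference) -> np.ndarray:
    """Flip the sign of each quaternion whose dot product with ``reference``
    is negative (both encode the same rotation; this picks the hemisphere of
    the reference so that componentwise averaging is well defined)."""
    q = _as_quat(q)
    reference = _as_quat(reference, "reference")
    dots = np.sum(q * reference, axis=-1, keepdims=True)
    return np.where(dots < 0.0, -q, q)


def sign_continuity(sequence, axis: int = 0) -> np.ndarray:
    """Enforce frame-to-frame sign continuity along ``axis``.

    Each quaternion is flipped when its dot product with the (already
    aligned) previous frame is negative, stabilizing averaging and
    regression across the double cover.
    """
    seq = _as_quat(sequence).copy()
    seq = np.moveaxis(seq, axis, 0)
    for t in range(1, seq.shape[0]):
        dots = np.sum(seq[t] * seq[t - 1], axis=-1, keepdims=True)
        seq[t] = np.where(dots < 0.0, -seq[t], seq[t])
    return np.moveaxis(seq, 0, axis)
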