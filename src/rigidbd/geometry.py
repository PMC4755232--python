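"""Rigid-body geometry: quaternions, rotations, and pose transforms.

Orientations are stored as unit quaternions (scalar-first, ``[w, x, y, z]``)
and converted to 3x3 proper rotation matrices for coordinate transforms.
Quaternions are renormalised after every update, which keeps long products
of incremental rotations orthonormal.  All functions broadcast over leading
axes so that batches of poses can be propagated in lockstep.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_normalize",
    "quat_multiply",
    "quat_to_matrix",
    "quat_from_rotvec",
    "quat_identity",
    "random_orientation",
    "random_quaternion",
    "rotate_vectors",
    "apply_pose",
    "assert_rotation_matrix",
]

_ORTHO_TOL = 1e-9


def quat_identity(shape: tuple[int, ...] = ()) -> np.ndarray:
    """Identity quaternion(s) of the given leading shape."""
    q = np.zeros(shape + (4,))
    q[..., 0] = 1.0
    return q


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero quaternion cannot be normalized")
    return q / norm


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b (apply b's rotation first, then a's)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = (a[..., i] for i in range(4))
    w2, x2, y2, z2 = (b[..., i] for i in range(4))
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (batched) from unit quaternion(s)."""
    q = quat_normalize(q)
    w, x, y, z = (q[..., i] for i in range(4))
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_from_rotvec(w: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation vector (axis * angle, rad).

    Exponential map; safe at zero angle via the series for sin(t/2)/t.
    """
    w = np.asarray(w, dtype=float)
    angle = np.linalg.norm(w, axis=-1, keepdims=True)
    half = 0.5 * angle
    small = angle < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(small, 0.5 - angle**2 / 48.0, np.sin(half) / np.where(angle == 0, 1.0, angle))
    q = np.concatenate([np.cos(half), scale * w], axis=-1)
    return quat_normalize(q)


def random_quaternion(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniformly distributed unit quaternion(s) (Shoemake's method)."""
    shape = () if n is None else (n,)
    u1, u2, u3 = (rng.random(shape) for _ in range(3))
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    q = np.stack(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ],
        axis=-1,
    )
    return q


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """A 3x3 rotation matrix drawn uniformly from SO(3)."""
    return quat_to_matrix(random_quaternion(rng))


def assert_rotation_matrix(m: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    """Raise ValueError unless m is a proper rotation (orthonormal, det=+1)."""
    m = np.asarray(m, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise ValueError(f"orientation must be 3x3, got {m.shape}")
    err = np.abs(m @ np.swapaxes(m, -1, -2) - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"orientation is not orthonormal (deviation {err:.2e})")
    det = np.linalg.det(m)
    if np.any(np.abs(det - 1.0) > tol):
        raise ValueError("orientation must have determinant +1")


def rotate_vectors(q: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Rotate body-frame points by quaternion(s) q.

    Shapes: q (..., 4), points (m, 3) -> (..., m, 3).
    """
    m = quat_to_matrix(q)
    return np.einsum("...ij,mj->...mi", m, np.asarray(points, dtype=float))


def apply_pose(points: np.ndarray, state) -> np.ndarray:
    """Map body-frame points to the lab frame: R @ p + x.

    ``state`` is a :class:`rigidbd.model.RigidBodyState`.  Distances between
    points are preserved exactly (up to floating point) since the transform
    is rigid.
    """
    m = state.rotation_matrix()
    assert_rotation_matrix(m)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return points @ m.T + state.position
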