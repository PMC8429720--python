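"""Unit-quaternion helpers in (w, x, y, z) convention.

scipy's Rotation uses (x, y, z, w); these wrappers keep the scalar-first
convention used throughout the package (identity = (1, 0, 0, 0)) and add
the Shoemake subgroup-algorithm sampler for rotations uniform on SO(3).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _check_unit(q: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError(f"quaternion must be a 4-vector, got shape {q.shape}")
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > tol:
        raise ValueError(f"quaternion norm {norm!r} differs from 1 by more than {tol}")
    return q


def as_rotation(q) -> Rotation:
    q = _check_unit(q)
    return Rotation.from_quat([q[1], q[2], q[3], q[0]])


def to_matrix(q) -> np.ndarray:
    return as_rotation(q).as_matrix()


def multiply(q1, q2) -> np.ndarray:
    """Composition: rotation q1 applied after q2."""
    r = as_rotation(q1) * as_rotation(q2)
    x, y, z, w = r.as_quat()
    return np.array([w, x, y, z])


def conjugate(q) -> np.ndarray:
    q = _check_unit(q)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def from_axis_angle(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    r = Rotation.from_rotvec(axis * angle_rad)
    x, y, z, w = r.as_quat()
    return np.array([w, x, y, z])


def random_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n quaternions uniform on SO(3) (Shoemake's subgroup algorithm)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u1, u2, u3 = rng.random((3, n))
    s1, s2 = np.sqrt(1.0 - u1), np.sqrt(u1)
    q = np.stack(
        [
            s2 * np.cos(2 * np.pi * u3),  # w
            s1 * np.sin(2 * np.pi * u2),
            s1 * np.cos(2 * np.pi * u2),
            s2 * np.sin(2 * np.pi * u3),
        ],
        axis=1,
    )
    return q
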