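"""Shared small geometry utilities: sphere point sets, local frames, rotations."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (deterministic golden-spiral set)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = GOLDEN_ANGLE * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.where(n == 0, 1.0, n)


def frame_from_z(z: np.ndarray, x_hint: np.ndarray | None = None) -> np.ndarray:
    """Right-handed orthonormal frame (columns x, y, z) with given z axis.

    The in-plane x axis is the projection of ``x_hint`` onto the plane normal
    to z; a fixed fallback axis is used when the hint is (anti)parallel to z.
    """
    z = np.asarray(z, dtype=float)
    z = z / np.linalg.norm(z)
    if x_hint is None:
        x_hint = np.array([1.0, 0.0, 0.0])
    x = np.asarray(x_hint, dtype=float) - np.dot(x_hint, z) * z
    if np.linalg.norm(x) < 1e-8:
        alt = np.array([0.0, 1.0, 0.0])
        x = alt - np.dot(alt, z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def frames_from_z(zs: np.ndarray, x_hints: np.ndarray | None = None) -> np.ndarray:
    out = np.empty((len(zs), 3, 3))
    for i, z in enumerate(zs):
        hint = None if x_hints is None else x_hints[i]
        out[i] = frame_from_z(z, hint)
    return out


def rotmats_to_quats(mats: np.ndarray) -> np.ndarray:
    """(N,3,3) -> (N,4) unit quaternions in (w, x, y, z) order with w >= 0."""
    q = Rotation.from_matrix(mats).as_quat()  # scipy: (x, y, z, w)
    q = np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])
    flip = q[:, 0] < 0
    q[flip] *= -1.0
    return q


def quats_to_rotmats(quats: np.ndarray) -> np.ndarray:
    """(N,4) (w,x,y,z) quaternions -> (N,3,3) rotation matrices."""
    q = np.asarray(quats, dtype=float)
    xyzw = np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]])
    return Rotation.from_quat(xyzw).as_matrix()


def rotation_angle(R: np.ndarray) -> float:
    """Magnitude (radians) of the rotation encoded by a 3x3 matrix."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def euler_zyz_from_matrix(mats: np.ndarray) -> np.ndarray:
    """Rotation matrices -> intrinsic ZYZ Euler angles in degrees."""
    return Rotation.from_matrix(mats).as_euler("ZYZ", degrees=True)


def matrix_from_euler_zyz(angles_deg: np.ndarray) -> np.ndarray:
    return Rotation.from_euler("ZYZ", angles_deg, degrees=True).as_matrix()
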