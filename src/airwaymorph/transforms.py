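"""Six-DOF rigid transforms and their Euler decomposition.

Axis convention (fixed for the whole package, millimetres / degrees):

* +x — patient right (lateral)
* +y — anterior (antero-posterior, AP); advancement positive, setback negative
* +z — cranial (cranio-caudal)

Angles follow the intrinsic z-y-x order: yaw about z, then roll about the
rotated y, then pitch about the rotated x, i.e. ``R = Rz(yaw) @ Ry(roll) @
Rx(pitch)``.  The decomposition is the exact inverse of the composition
except at gimbal lock (|roll| = 90 deg), where yaw is conventionally set to
zero and the result is flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "euler_compose", "euler_decompose", "random_pose"]

_ORTHO_TOL = 1e-8


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_compose(
    pitch: float, roll: float, yaw: float, tx: float, ty: float, tz: float
) -> np.ndarray:
    """Build a 4x4 homogeneous matrix from angles (degrees) and translation (mm)."""
    p, r, y = np.deg2rad([pitch, roll, yaw])
    m = np.eye(4)
    m[:3, :3] = _rot_z(y) @ _rot_y(r) @ _rot_x(p)
    m[:3, 3] = (tx, ty, tz)
    return m


def _check_rigid(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 homogeneous matrix, got shape {m.shape}")
    r = m[:3, :3]
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation block is not orthonormal")
    if np.linalg.det(r) < 0:
        raise ValueError("rotation block has determinant -1 (reflection)")
    if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
        raise ValueError("bottom row of homogeneous matrix must be [0, 0, 0, 1]")
    return m


def euler_decompose(matrix: np.ndarray) -> "RigidTransform":
    """Decompose a rigid 4x4 matrix into (pitch, roll, yaw, tx, ty, tz).

    At gimbal lock (|roll| = 90 deg) yaw is set to 0 and the returned
    transform carries ``gimbal_lock=True``; pitch absorbs the remaining
    rotation.
    """
    m = _check_rigid(matrix)
    r = m[:3, :3]
    sin_roll = np.clip(-r[2, 0], -1.0, 1.0)
    roll = np.arcsin(sin_roll)
    gimbal = abs(abs(sin_roll) - 1.0) < 1e-9
    if not gimbal:
        pitch = np.arctan2(r[2, 1], r[2, 2])
        yaw = np.arctan2(r[1, 0], r[0, 0])
    else:
        yaw = 0.0
        if sin_roll > 0:  # roll = +90
            pitch = np.arctan2(r[0, 1], r[0, 2])
        else:  # roll = -90
            pitch = np.arctan2(-r[0, 1], -r[0, 2])
    pitch, roll, yaw = np.rad2deg([pitch, roll, yaw])
    return RigidTransform(
        pitch=float(pitch),
        roll=float(roll),
        yaw=float(yaw),
        tx=float(m[0, 3]),
        ty=float(m[1, 3]),
        tz=float(m[2, 3]),
        gimbal_lock=bool(gimbal),
    )


@dataclass(frozen=True)
class RigidTransform:
    """Rigid pose: rotations in degrees about x (pitch), y (roll), z (yaw),
    translations in mm; ``ty`` is the antero-posterior (AP) component."""

    pitch: float = 0.0
    roll: float = 0.0
    yaw: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    gimbal_lock: bool = field(default=False, compare=False)

    @property
    def matrix(self) -> np.ndarray:
        return euler_compose(self.pitch, self.roll, self.yaw, self.tx, self.ty, self.tz)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        return euler_decompose(matrix)

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return euler_decompose(m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out if np.asarray(points).ndim == 2 else out[0]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return euler_decompose(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        m = self.matrix
        inv = np.eye(4)
        inv[:3, :3] = m[:3, :3].T
        inv[:3, 3] = -m[:3, :3].T @ m[:3, 3]
        return euler_decompose(inv)

    @property
    def ap(self) -> float:
        """Antero-posterior translation (alias of ty, mm)."""
        return self.ty


def random_pose(
    rng: np.random.Generator,
    max_angle_deg: float = 30.0,
    max_translation_mm: float = 10.0,
) -> RigidTransform:
    """Uniform-ish random rigid pose, used by tests and the cohort simulator."""
    angles = rng.uniform(-max_angle_deg, max_angle_deg, 3)
    trans = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    return RigidTransform(*angles, *trans)
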