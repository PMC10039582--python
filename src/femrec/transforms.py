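"""Rigid transforms and small vector-geometry helpers.

The anatomical frame used throughout the package is right handed with
``x`` pointing medial to lateral, ``y`` posterior to anterior and ``z``
distal to proximal (all coordinates in millimetres).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "rotation_about_axis",
    "angle_between",
    "line_angle",
    "unit",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalised to unit length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise the zero vector")
    return v / n


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    a = unit(a)
    b = unit(b)
    # atan2 formulation is well conditioned near 0 and 180 degrees
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(a, b)), np.dot(a, b))))


def line_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two undirected lines in degrees, in [0, 90]."""
    ang = angle_between(a, b)
    return min(ang, 180.0 - ang)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    k = unit(axis)
    t = np.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1.0 - np.cos(t)) * (kx @ kx)


@dataclass
class RigidTransform:
    """Proper rigid transform ``p -> R p + t`` in millimetres."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be a proper rotation (det = +1)")
        if np.abs(self.rotation @ self.rotation.T - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle(self) -> float:
        """Magnitude of the rotation in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
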