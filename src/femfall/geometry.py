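"""Rigid transforms and small linear-geometry helpers.

Conventions used throughout the package: 0-based voxel indices,
world = origin + index * spacing, axis order (x, y, z); all meshes and
points in world millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "closest_points_between_lines", "rotation_between_frames"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map p -> R @ p + t (millimetres).

    ``rotation`` must be proper orthogonal (det = +1); this is validated on
    construction to 1e-9.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthogonal (det = +1)")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    # serialization ---------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = json.dumps({"rotation": self.rotation.tolist(),
                              "translation": self.translation.tolist()}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "RigidTransform":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(np.array(d["rotation"]), np.array(d["translation"]))

    # parameter helpers -----------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_between_frames(src_basis: np.ndarray, dst_basis: np.ndarray) -> np.ndarray:
    """Rotation mapping the orthonormal columns of ``src_basis`` onto ``dst_basis``."""
    U = np.asarray(src_basis, float)
    V = np.asarray(dst_basis, float)
    return V @ U.T


def closest_points_between_lines(p1, d1, p2, d2):
    """Closest points on two lines (point, unit direction); returns (q1, q2, gap)."""
    p1, d1, p2, d2 = (np.asarray(a, float) for a in (p1, d1, p2, d2))
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    r = p2 - p1
    a = d1 @ d2
    denom = 1.0 - a * a
    if denom < 1e-12:  # parallel: project p2 on line 1
        t1 = r @ d1
        q1 = p1 + t1 * d1
        return q1, p2, float(np.linalg.norm(q1 - p2))
    t1 = (r @ d1 - a * (r @ d2)) / denom
    t2 = (a * (r @ d1) - r @ d2) / denom
    q1 = p1 + t1 * d1
    q2 = p2 + t2 * d2
    return q1, q2, float(np.linalg.norm(q1 - q2))
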