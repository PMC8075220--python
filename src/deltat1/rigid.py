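"""Rigid (6-DOF) voxel-space transforms for pre/post misalignment.

A :class:`RigidTransform` moves an object by rotating it about a centre
point and translating it: ``T(x) = R (x - c) + c + t`` with ``x`` in voxel
coordinates (numpy index order).  Applying ``T`` to a volume resamples it as
``g(x) = f(T^-1(x))`` with trilinear interpolation, i.e. the returned image
shows the object displaced by ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["RigidTransform"]


def _rotation_matrix(rotation_deg) -> np.ndarray:
    """Rotation composed about numpy axes 0, 1, 2 (applied in that order)."""
    rx, ry, rz = np.radians(rotation_deg)
    c, s = np.cos(rx), np.sin(rx)
    r0 = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    c, s = np.cos(ry), np.sin(ry)
    r1 = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    c, s = np.cos(rz), np.sin(rz)
    r2 = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    return r2 @ r1 @ r0


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion ``x -> R (x - center) + center + translation`` (voxels)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, float))
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        object.__setattr__(self, "center", np.asarray(self.center, float))

    @classmethod
    def from_params(
        cls,
        translation_vox=(0.0, 0.0, 0.0),
        rotation_deg=(0.0, 0.0, 0.0),
        center_vox=(0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        return cls(
            matrix=_rotation_matrix(rotation_deg),
            translation=np.asarray(translation_vox, float),
            center=np.asarray(center_vox, float),
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.matrix, np.eye(3)) and np.allclose(self.translation, 0.0)
        )

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix.T
        return RigidTransform(
            matrix=rinv, translation=-rinv @ self.translation, center=self.center
        )

    def apply_to(self, data: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Resample ``data`` so the object appears moved by this transform."""
        if self.is_identity:
            return np.asarray(data, float).copy()
        rinv = self.matrix.T
        offset = self.center - rinv @ (self.center + self.translation)
        return ndimage.affine_transform(
            np.asarray(data, float), rinv, offset=offset, order=order, cval=cval,
            mode="constant",
        )

    def as_homogeneous(self) -> np.ndarray:
        """4x4 voxel-space matrix of the forward map."""
        mat = np.eye(4)
        mat[:3, :3] = self.matrix
        mat[:3, 3] = self.center + self.translation - self.matrix @ self.center
        return mat

    def to_world(self, affine: np.ndarray) -> np.ndarray:
        """4x4 world-space (mm) matrix of the forward map for a given affine."""
        affine = np.asarray(affine, float)
        return affine @ self.as_homogeneous() @ np.linalg.inv(affine)

    @classmethod
    def from_homogeneous(cls, mat: np.ndarray) -> "RigidTransform":
        mat = np.asarray(mat, float)
        return cls(matrix=mat[:3, :3], translation=mat[:3, 3], center=np.zeros(3))
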