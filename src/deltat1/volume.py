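"""In-memory 3D volumes, tissue/lesion mask algebra, and the ΔT1 map type.

A :class:`Volume` is a 3D scalar grid with a voxel-to-world affine (mm) and a
unit tag (``"s"`` for relaxation-time maps, ``"dimensionless"`` for UNI
images, ``"signal"`` for raw GRE magnitudes).  Masks are plain boolean numpy
arrays living on the same grid; :class:`MaskSet` groups the analysis regions
(WML, EL, NEL, NAWM, cGM, cerebral WM) and enforces their set-algebra
invariants: NEL = WML minus EL, NAWM is disjoint from WML, EL is a subset of
WML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, GeometryError

__all__ = ["Volume", "MaskSet", "DeltaT1Map", "derive_masks"]

UNITS = ("s", "dimensionless", "signal")


@dataclass
class Volume:
    """A 3D scalar grid with affine geometry and a unit tag."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        if self.units not in UNITS:
            raise ConfigurationError(f"unknown unit tag {self.units!r}; use one of {UNITS}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "Volume") -> None:
        if not self.same_grid(other):
            raise GeometryError(
                f"volumes are not on the same grid: {self.shape} vs {other.shape}"
            )

    def with_data(self, data: np.ndarray, units: str | None = None) -> "Volume":
        return replace(self, data=np.asarray(data, float), units=units or self.units)


@dataclass
class MaskSet:
    """Boolean analysis regions on a shared grid.

    ``wml`` is the full white-matter-lesion mask, ``el`` the enhancing-lesion
    subset, ``nel`` the non-enhancing remainder, ``nawm`` normal-appearing
    white matter (cerebral WM minus WML), ``cgm`` cortical gray matter.
    """

    wml: np.ndarray
    el: np.ndarray
    nel: np.ndarray
    nawm: np.ndarray
    cgm: np.ndarray
    cerebral_wm: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.as_dict().values()}
        if len(shapes) != 1:
            raise GeometryError(f"masks are not on a shared grid: {shapes}")
        for name, mask in self.as_dict().items():
            if mask.dtype != bool:
                setattr(self, name, mask.astype(bool))
        if np.any(self.el & ~self.wml):
            raise ConfigurationError("EL mask is not a subset of the WML mask")
        if np.any(self.nel != (self.wml & ~self.el)):
            raise ConfigurationError("NEL mask must equal WML AND NOT EL")
        if np.any(self.nawm & self.wml):
            raise ConfigurationError("NAWM and WML masks overlap")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "wml": self.wml,
            "el": self.el,
            "nel": self.nel,
            "nawm": self.nawm,
            "cgm": self.cgm,
            "cerebral_wm": self.cerebral_wm,
        }

    def __getitem__(self, tissue: str) -> np.ndarray:
        try:
            return self.as_dict()[tissue.lower()]
        except KeyError:
            raise KeyError(f"unknown tissue {tissue!r}; known: {sorted(self.as_dict())}")


@dataclass
class DeltaT1Map:
    """Voxelwise post-minus-pre T1 difference (seconds).

    Negative values mean gadolinium-induced T1 shortening.  Voxels excluded
    by reconstruction QC are NaN and treated as missing downstream.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    provenance: dict = field(default_factory=dict)

    def as_volume(self) -> Volume:
        return Volume(self.data, self.affine, units="s")


def derive_masks(
    wml: np.ndarray,
    el: np.ndarray,
    cerebral_wm: np.ndarray,
    cgm: np.ndarray,
) -> MaskSet:
    """Derive the analysis mask set from the four primary masks.

    NEL is the WML mask with enhancing lesions subtracted; NAWM is cerebral
    white matter with all lesions subtracted.  If EL protrudes outside WML it
    is clipped to the intersection with a warning (delineation masks drawn on
    different images may disagree by a voxel at the rim).
    """
    wml = np.asarray(wml, bool)
    el = np.asarray(el, bool)
    cerebral_wm = np.asarray(cerebral_wm, bool)
    cgm = np.asarray(cgm, bool)
    if not (wml.shape == el.shape == cerebral_wm.shape == cgm.shape):
        raise GeometryError("primary masks are not on a shared grid")
    if not cerebral_wm.any():
        raise ConfigurationError("cerebral WM mask is empty")
    if np.any(el & ~wml):
        warnings.warn(
            "EL mask extends outside the WML mask; clipping to the intersection",
            stacklevel=2,
        )
        el = el & wml
    return MaskSet(
        wml=wml,
        el=el,
        nel=wml & ~el,
        nawm=cerebral_wm & ~wml,
        cgm=cgm,
        cerebral_wm=cerebral_wm,
    )
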