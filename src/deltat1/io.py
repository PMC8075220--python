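"""On-disk formats: NIfTI-1 volumes and masks, 4x4 text transforms, and
comma-separated tables with a provenance comment header.

Every file written by the package carries provenance: volumes encode their
unit tag and the run's seed/config hash in the NIfTI ``descrip`` field
(80 bytes, ``key=value`` pairs separated by ``|``); tables carry a leading
``#`` comment line with the same pairs.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError
from .rigid import RigidTransform
from .volume import Volume

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_transform",
    "read_transform",
    "write_table",
    "read_table",
]


def _descrip(units: str, provenance: dict | None) -> bytes:
    pairs = [f"units={units}"] + [
        f"{k}={v}" for k, v in (provenance or {}).items()
    ]
    return "|".join(pairs).encode()[:79]


def write_volume(volume: Volume, path: str | Path, provenance: dict | None = None) -> None:
    """Write a volume as NIfTI-1, embedding units and provenance."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.header["descrip"] = _descrip(volume.units, provenance)
    nib.save(img, str(path))


def read_volume(path: str | Path, units: str | None = None) -> Volume:
    """Read a NIfTI-1 volume; units come from the header unless overridden.

    A missing unit tag falls back to ``dimensionless`` with a warning; a
    malformed or truncated file raises :class:`FormatError`.
    """
    import warnings

    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several unrelated types here
        raise FormatError(f"could not read {path} as NIfTI-1: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if units is None:
        descrip = img.header["descrip"].tobytes().decode(errors="replace")
        units = "dimensionless"
        for pair in descrip.strip("\x00").split("|"):
            if pair.startswith("units="):
                units = pair.split("=", 1)[1]
                break
        else:
            warnings.warn(f"{path}: no unit tag in header; assuming dimensionless")
    return Volume(data, img.affine, units=units)


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path,
               provenance: dict | None = None) -> None:
    """Write a boolean mask as a uint8 NIfTI-1 volume."""
    img = nib.Nifti1Image(np.asarray(mask, np.uint8), np.asarray(affine, float))
    img.header["descrip"] = _descrip("dimensionless", provenance)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    try:
        img = nib.load(str(path))
        return np.asanyarray(img.dataobj) > 0
    except Exception as exc:
        raise FormatError(f"could not read {path} as a mask: {exc}") from exc


def write_transform(transform: RigidTransform, affine: np.ndarray, path: str | Path) -> None:
    """Store a rigid transform as its 4x4 world-coordinate (mm) matrix."""
    np.savetxt(str(path), transform.to_world(affine), fmt="%.12g")


def read_transform(path: str | Path, affine: np.ndarray) -> RigidTransform:
    """Load a 4x4 world-coordinate matrix back into a voxel-space transform."""
    try:
        world = np.loadtxt(str(path))
    except Exception as exc:
        raise FormatError(f"could not read {path} as a 4x4 transform: {exc}") from exc
    if world.shape != (4, 4):
        raise FormatError(f"{path}: expected a 4x4 matrix, got {world.shape}")
    affine = np.asarray(affine, float)
    vox = np.linalg.inv(affine) @ world @ affine
    return RigidTransform.from_homogeneous(vox)


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a comma-separated table with a '#' provenance header line."""
    path = Path(path)
    header = "# " + ", ".join(f"{k}={v}" for k, v in (provenance or {}).items())
    with path.open("w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(str(path), comment="#", **kwargs)
    except Exception as exc:
        raise FormatError(f"could not read {path} as a table: {exc}") from exc
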