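"""Calibrated 3D scalar volumes (Hounsfield units) with simple NIfTI/MetaImage io."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

AIR_HU = -1000.0


class VolumeError(ValueError):
    pass


@dataclass
class VolumeImage:
    """Axis-aligned scalar volume.

    ``scalars[i, j, k]`` sits at world position ``origin + (i, j, k) * spacing``;
    the array axes follow the anatomical frame axes (x, y, z).
    """

    scalars: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    frame: str = "xyz:ML,PA,DP"

    def __post_init__(self) -> None:
        self.scalars = np.ascontiguousarray(self.scalars, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.scalars.ndim != 3:
            raise VolumeError("scalars must be a 3D array")
        if (self.spacing <= 0).any():
            raise VolumeError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.scalars.shape

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), hi

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def sample_nearest(self, points: np.ndarray) -> np.ndarray:
        """Value of the voxel whose centre is nearest each point (no interpolation)."""
        idx = np.rint(self.world_to_index(points)).astype(int)
        shape = np.array(self.shape)
        if (idx < 0).any() or (idx >= shape).any():
            bad = np.nonzero(((idx < 0) | (idx >= shape)).any(axis=1))[0]
            raise VolumeError(f"{len(bad)} points outside the volume (first: {bad[:10].tolist()})")
        return self.scalars[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)

    # -- io -------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".mha":
            _write_mha(self, path)
        else:
            _write_nifti(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "VolumeImage":
        path = Path(path)
        if path.suffix == ".mha":
            return _read_mha(path)
        return _read_nifti(path)


def _write_nifti(vol: VolumeImage, path: Path) -> None:
    import nibabel as nib

    affine = np.diag(np.append(vol.spacing, 1.0))
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.scalars, affine), str(path))


def _read_nifti(path: Path) -> VolumeImage:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    return VolumeImage(np.asarray(img.dataobj, dtype=np.float32), spacing, affine[:3, 3])


def _write_mha(vol: VolumeImage, path: Path) -> None:
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        "TransformMatrix = 1 0 0 0 1 0 0 0 1\n"
        f"Offset = {vol.origin[0]} {vol.origin[1]} {vol.origin[2]}\n"
        f"ElementSpacing = {vol.spacing[0]} {vol.spacing[1]} {vol.spacing[2]}\n"
        f"DimSize = {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}\n"
        "ElementType = MET_FLOAT\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode())
        # MetaImage stores the fastest-varying index first
        fh.write(np.ascontiguousarray(vol.scalars.transpose(2, 1, 0)).tobytes())


def _read_mha(path: Path) -> VolumeImage:
    meta: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline().decode()
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                break
        dims = [int(x) for x in meta["DimSize"].split()]
        data = np.frombuffer(fh.read(), dtype=np.float32)
    scalars = data.reshape(dims[::-1]).transpose(2, 1, 0)
    spacing = [float(x) for x in meta["ElementSpacing"].split()]
    origin = [float(x) for x in meta.get("Offset", "0 0 0").split()]
    return VolumeImage(scalars, spacing, origin)
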