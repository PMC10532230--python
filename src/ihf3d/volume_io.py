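"""3D volume and mask containers with NIfTI input/output.

A :class:`Volume` is a plain 3D scalar grid (CT intensities in Hounsfield
units, MRI in arbitrary units) paired with per-axis voxel spacing in mm.
The three grid axes are treated abstractly and positionally: no anatomical
reorientation is performed, because the downstream method uses only the
intensity distribution and the physical voxel size.  Affine headers beyond
spacing (rotation, origin) are carried through on write but ignored by all
computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "MaskVolume", "read_volume", "write_volume", "read_mask", "write_mask"]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing components must be strictly positive and finite, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm per axis."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"unsupported dimensionality: expected 3 axes, got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("corrupt input: volume contains non-finite intensities")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class MaskVolume:
    """A 3D binary occupancy grid with the same spacing conventions as Volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"unsupported dimensionality: expected 3 axes, got {self.data.ndim}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be exactly 0 or 1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"unsupported dimensionality: expected a 3D image, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.float64), spacing, np.asarray(img.affine)


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI image; spacing is taken from the header, intensities unmodified."""
    data, spacing, affine = _load_nifti(path)
    return Volume(data=data, spacing=spacing, affine=affine)


def _spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1; re-reading yields identical data and spacing."""
    affine = v.affine if v.affine is not None else _spacing_affine(v.spacing)
    img = nib.Nifti1Image(v.data.astype(np.float64), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> MaskVolume:
    """Read a binary 3D NIfTI mask; near-binary values are binarized at 0.5 with a warning."""
    data, spacing, affine = _load_nifti(path)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        warnings.warn(
            f"mask at {path} is not strictly binary (values outside {{0,1}}); binarizing at 0.5",
            stacklevel=2,
        )
        data = (data > 0.5).astype(np.uint8)
    return MaskVolume(data=data.astype(np.uint8), spacing=spacing, affine=affine)


def write_mask(m: MaskVolume, path: str | Path) -> None:
    affine = m.affine if m.affine is not None else _spacing_affine(m.spacing)
    img = nib.Nifti1Image(m.data.astype(np.uint8), affine)
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))
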