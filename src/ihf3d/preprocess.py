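"""Intensity standardization pipeline: resample -> clip -> MinMax scale.

Every image, regardless of origin, is mapped onto a common grid and a common
[0, 1] intensity range before histogramming:

1. trilinear resampling to a target spacing (default 1 x 1 x 1.5 mm, a typical
   median spacing for chest CT / brain MRI cohorts);
2. intensity clipping — a fixed [-1350, 300] HU lung window for CT, the
   per-image [1st, 99th] intensity percentiles for MRI (whose units are
   scanner-arbitrary);
3. MinMax scaling of the clipped image to [0, 1].

The stage order is fixed; clipping before scaling guarantees the [0, 1]
output range for any input.  A constant image scales to all zeros so the
downstream histogram stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import MaskVolume, Volume

__all__ = ["PreprocessConfig", "resample", "resample_mask", "clip_intensities", "minmax_scale", "preprocess"]

DEFAULT_SPACING = (1.0, 1.0, 1.5)
CT_WINDOW = (-1350.0, 300.0)  # standard lung window, HU
MRI_PERCENTILES = (1.0, 99.0)


@dataclass
class PreprocessConfig:
    """Configuration of the standardization pipeline."""

    modality: str = "CT"
    target_spacing: tuple[float, float, float] = DEFAULT_SPACING
    ct_window: tuple[float, float] = CT_WINDOW
    mri_percentiles: tuple[float, float] = MRI_PERCENTILES

    def __post_init__(self) -> None:
        self.modality = self.modality.upper()
        if self.modality not in ("CT", "MRI"):
            raise ValueError(f"modality must be 'CT' or 'MRI', got {self.modality!r}")
        if not all(s > 0 for s in self.target_spacing):
            raise ValueError(f"target_spacing must be strictly positive, got {self.target_spacing}")
        lo, hi = self.ct_window
        if not lo < hi:
            raise ValueError(f"ct_window low must be < high, got {self.ct_window}")
        p_lo, p_hi = self.mri_percentiles
        if not 0 <= p_lo < p_hi <= 100:
            raise ValueError(f"mri_percentiles must satisfy 0 <= low < high <= 100, got {self.mri_percentiles}")


def _output_shape(shape: tuple[int, ...], spacing: tuple[float, ...], target: tuple[float, ...]) -> tuple[int, ...]:
    # round(n * s_in / s_target), half away from zero, at least 1 voxel
    out = []
    for n, s_in, s_t in zip(shape, spacing, target):
        out.append(max(1, int(np.floor(n * s_in / s_t + 0.5))))
    return tuple(out)


def _resample_data(data: np.ndarray, spacing, target, order: int) -> np.ndarray:
    out_shape = _output_shape(data.shape, spacing, target)
    if out_shape == data.shape and tuple(spacing) == tuple(target):
        return data.copy()
    # output voxel i sits at physical position i*s_target, i.e. input index i*s_target/s_in
    grids = [
        np.arange(n_out, dtype=np.float64) * (s_t / s_in)
        for n_out, s_t, s_in in zip(out_shape, target, spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    return ndimage.map_coordinates(data, coords, order=order, mode="nearest")


def resample(v: Volume, target_spacing: tuple[float, float, float]) -> Volume:
    """Trilinearly resample a volume onto the target spacing.

    The output has shape round(n_in * s_in / s_target) per axis (minimum 1);
    edge voxels are extended (nearest) where the output grid overshoots the
    input extent.
    """
    if not all(s > 0 for s in target_spacing):
        raise ValueError(f"target spacing must be strictly positive, got {target_spacing}")
    data = _resample_data(v.data, v.spacing, target_spacing, order=1)
    return Volume(data=data, spacing=tuple(target_spacing), affine=None)


def resample_mask(m: MaskVolume, target_spacing: tuple[float, float, float]) -> MaskVolume:
    """Nearest-neighbor resampling for binary masks (keeps values in {0, 1})."""
    if not all(s > 0 for s in target_spacing):
        raise ValueError(f"target spacing must be strictly positive, got {target_spacing}")
    data = _resample_data(m.data.astype(np.float64), m.spacing, target_spacing, order=0)
    return MaskVolume(data=data.astype(np.uint8), spacing=tuple(target_spacing), affine=None)


def clip_intensities(v: Volume, config: PreprocessConfig) -> Volume:
    """Clip intensities to the modality-specific window.

    CT uses the fixed HU window from the config; MRI uses the image's own
    [p_low, p_high] intensity percentiles (linear-interpolation convention),
    since MRI units are not calibrated across scanners.
    """
    if config.modality == "CT":
        lo, hi = config.ct_window
    else:
        lo, hi = np.percentile(v.data, config.mri_percentiles)
    return Volume(data=np.clip(v.data, lo, hi), spacing=v.spacing, affine=v.affine)


def minmax_scale(v: Volume) -> Volume:
    """Map intensities affinely so min -> 0 and max -> 1; a constant image maps to zeros."""
    lo = float(v.data.min())
    hi = float(v.data.max())
    if hi == lo:
        data = np.zeros_like(v.data)
    else:
        data = (v.data - lo) / (hi - lo)
    return Volume(data=data, spacing=v.spacing, affine=v.affine)


def preprocess(v: Volume, config: PreprocessConfig) -> Volume:
    """Full pipeline: resample -> clip -> MinMax scale.  Output intensities lie in [0, 1]."""
    out = resample(v, config.target_spacing)
    out = clip_intensities(out, config)
    return minmax_scale(out)
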