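"""Synthetic OOD corruption operators for 3D volumes.

Six families of seeded, deterministic image corruptions emulate acquisition
artifacts and tissue anomalies at five perceptual severity levels (1 =
barely noticeable, 5 = heavily distorted):

- ``local_noise`` — blur, contrast (gamma) change or Gaussian noise inside a
  random axis-aligned crop (CT-style local image corruption);
- ``elastic``    — smooth random elastic deformation from a coarse control
  grid (tissue anomaly);
- ``kspace``     — complex spikes at random spatial frequencies (MRI
  Herringbone artifact);
- ``anisotropy`` — down/upsampling along one random axis (wrong resolution);
- ``ghosting``   — attenuated circularly shifted copies along one axis
  (MRI motion ghosts);
- ``motion``     — k-space segments replaced by rigidly perturbed copies of
  the volume (mid-acquisition patient motion).

Corruptions operate on raw-intensity volumes (before preprocessing).  Shape
and spacing are always preserved, and identical (volume, kind, severity,
seed) produce bit-identical output.  The numeric parameter tables per level
are this package's own calibration and are exported as plain dicts so
severity sweeps are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume

__all__ = [
    "CORRUPTION_KINDS",
    "CorruptionSpec",
    "SEVERITY_TABLES",
    "corrupt",
    "corrupt_local",
    "corrupt_elastic",
    "corrupt_kspace",
    "corrupt_anisotropy",
    "corrupt_ghosting",
    "corrupt_motion",
]

CORRUPTION_KINDS = ("local_noise", "elastic", "kspace", "anisotropy", "ghosting", "motion")

# Per-level parameter tables (levels 1..5).  Level-0-style entries with all
# magnitudes zeroed act as identity and are permitted for testing.
SEVERITY_TABLES: dict[str, dict[int, dict[str, float]]] = {
    # blur sigma in voxels; gamma applied to the locally normalized crop;
    # noise sd as a fraction of the image intensity range
    "local_noise": {
        1: {"blur_sigma": 0.5, "gamma": 1.3, "noise_frac": 0.02},
        2: {"blur_sigma": 1.0, "gamma": 1.6, "noise_frac": 0.05},
        3: {"blur_sigma": 2.0, "gamma": 2.2, "noise_frac": 0.10},
        4: {"blur_sigma": 4.0, "gamma": 3.0, "noise_frac": 0.20},
        5: {"blur_sigma": 8.0, "gamma": 4.5, "noise_frac": 0.40},
    },
    # max control-point displacement in voxels, on an 8^3 control grid
    "elastic": {lvl: {"max_disp": d} for lvl, d in zip(range(1, 6), (1.0, 2.0, 4.0, 8.0, 16.0))},
    # spike count and image-domain sinusoid amplitude as a fraction of the mean intensity
    "kspace": {
        1: {"count": 1, "amp_frac": 0.05},
        2: {"count": 2, "amp_frac": 0.10},
        3: {"count": 4, "amp_frac": 0.20},
        4: {"count": 8, "amp_frac": 0.40},
        5: {"count": 16, "amp_frac": 0.80},
    },
    # down/upsampling factor along one axis
    "anisotropy": {lvl: {"factor": f} for lvl, f in zip(range(1, 6), (2, 3, 4, 6, 8))},
    # ghost weight w and number of ghosts G
    "ghosting": {
        1: {"w": 0.05, "ghosts": 2},
        2: {"w": 0.10, "ghosts": 2},
        3: {"w": 0.20, "ghosts": 3},
        4: {"w": 0.35, "ghosts": 3},
        5: {"w": 0.50, "ghosts": 4},
    },
    # number of rigid perturbations, max rotation (degrees), max translation (voxels)
    "motion": {
        1: {"transforms": 1, "rot_deg": 1.0, "trans_vox": 0.5},
        2: {"transforms": 1, "rot_deg": 2.0, "trans_vox": 1.0},
        3: {"transforms": 2, "rot_deg": 4.0, "trans_vox": 2.0},
        4: {"transforms": 2, "rot_deg": 8.0, "trans_vox": 4.0},
        5: {"transforms": 3, "rot_deg": 15.0, "trans_vox": 8.0},
    },
}


@dataclass
class CorruptionSpec:
    """One synthetic OOD source: kind, severity level 1-5, seed."""

    kind: str
    severity: int
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in CORRUPTION_KINDS:
            raise ValueError(f"unknown corruption kind {self.kind!r}; choose from {CORRUPTION_KINDS}")
        if not 1 <= self.severity <= 5:
            raise ValueError(f"severity must be in 1..5, got {self.severity}")


def _params(kind: str, severity: int, table) -> dict[str, float]:
    table = table if table is not None else SEVERITY_TABLES[kind]
    if severity not in table:
        raise ValueError(f"severity {severity} not in table for {kind}")
    return table[severity]


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_crop(rng: np.random.Generator, shape: tuple[int, ...]) -> tuple[slice, ...]:
    # crop extent: uniform fraction 0.1-0.5 of each axis, clamped to >= 1 voxel
    slices = []
    for n in shape:
        size = min(n, max(1, int(round(rng.uniform(0.1, 0.5) * n))))
        start = int(rng.integers(0, n - size + 1))
        slices.append(slice(start, start + size))
    return tuple(slices)


def corrupt_local(v: Volume, severity: int, seed: int, table=None, variant: str | None = None) -> Volume:
    """Blur, gamma-contrast change or Gaussian noise inside a random crop.

    The sub-transform is chosen by the seed unless ``variant`` forces one;
    voxels outside the crop are bit-identical to the input.  Noise sd is
    ``noise_frac`` times the image intensity range (unit range for constant
    images).
    """
    p = _params("local_noise", severity, table)
    rng = _rng(seed)
    crop = _random_crop(rng, v.shape)
    if variant is None:
        variant = rng.choice(["blur", "contrast", "noise"])
    elif variant not in ("blur", "contrast", "noise"):
        raise ValueError(f"unknown variant {variant!r}")
    out = v.data.copy()
    sub = out[crop]
    if variant == "blur" and p["blur_sigma"] > 0:
        out[crop] = ndimage.gaussian_filter(sub, sigma=p["blur_sigma"], mode="nearest")
    elif variant == "contrast" and p["gamma"] != 1.0:
        lo, hi = float(sub.min()), float(sub.max())
        if hi > lo:
            out[crop] = lo + (hi - lo) * ((sub - lo) / (hi - lo)) ** p["gamma"]
    elif variant == "noise" and p["noise_frac"] > 0:
        span = float(v.data.max() - v.data.min())
        sigma = p["noise_frac"] * (span if span > 0 else 1.0)
        out[crop] = sub + rng.normal(0.0, sigma, size=sub.shape)
    return Volume(data=out, spacing=v.spacing, affine=v.affine)


def corrupt_elastic(v: Volume, severity: int, seed: int, table=None, grid: int = 8) -> Volume:
    """Smooth elastic deformation from random offsets on a coarse control grid.

    Control-point offsets are uniform in [-d, d] voxels per axis (d from the
    severity table); trilinear upsampling keeps the dense displacement within
    the same bound everywhere.
    """
    p = _params("elastic", severity, table)
    d = p["max_disp"]
    rng = _rng(seed)
    offsets = rng.uniform(-d, d, size=(3, grid, grid, grid))
    if d == 0:
        return Volume(data=v.data.copy(), spacing=v.spacing, affine=v.affine)
    idx = np.indices(v.shape).astype(np.float64)
    coords = []
    for ax in range(3):
        # control grid spans the volume: voxel i -> control coordinate i*(grid-1)/(n-1)
        ctrl_coords = [
            idx[a] * ((grid - 1) / max(v.shape[a] - 1, 1)) for a in range(3)
        ]
        disp = ndimage.map_coordinates(offsets[ax], ctrl_coords, order=1, mode="nearest")
        coords.append(idx[ax] + disp)
    data = ndimage.map_coordinates(v.data, coords, order=1, mode="nearest")
    return Volume(data=data, spacing=v.spacing, affine=v.affine)


def _apply_spikes(data: np.ndarray, freqs: np.ndarray, amps: np.ndarray) -> np.ndarray:
    """Add complex spikes of given amplitudes at the given DFT frequencies and
    return the real part of the inverse transform."""
    F = np.fft.fftn(data)
    for f, a in zip(freqs, amps):
        F[tuple(f)] += a
    return np.real(np.fft.ifftn(F))


def corrupt_kspace(v: Volume, severity: int, seed: int, table=None) -> Volume:
    """Herringbone-style artifact: spikes at random non-DC spatial frequencies.

    Each spike adds a global sinusoid whose image-domain amplitude is
    ``amp_frac`` times the mean absolute intensity; the DC bin is untouched so
    the mean intensity is preserved.
    """
    p = _params("kspace", severity, table)
    count = int(p["count"])
    if count == 0 or p["amp_frac"] == 0:
        return Volume(data=v.data.copy(), spacing=v.spacing, affine=v.affine)
    rng = _rng(seed)
    n_total = v.data.size
    base = float(np.mean(np.abs(v.data)))
    if base == 0:
        base = 1.0
    freqs = []
    while len(freqs) < count:
        f = tuple(int(rng.integers(0, n)) for n in v.shape)
        if f != (0, 0, 0):
            freqs.append(f)
    phases = rng.uniform(0, 2 * np.pi, size=count)
    # k-space amplitude A gives an image-domain sinusoid of amplitude |A|/N
    amps = p["amp_frac"] * base * n_total * np.exp(1j * phases)
    data = _apply_spikes(v.data, np.array(freqs), amps)
    return Volume(data=data, spacing=v.spacing, affine=v.affine)


def _upsample_axis(down: np.ndarray, axis: int, n_out: int, factor: int, mode: str) -> np.ndarray:
    down = np.moveaxis(down, axis, -1)
    j = np.arange(n_out, dtype=np.float64) / factor
    if mode == "nearest":
        i0 = np.minimum(np.floor(j).astype(int), down.shape[-1] - 1)
        out = down[..., i0]
    else:
        i0 = np.floor(j).astype(int)
        i1 = np.minimum(i0 + 1, down.shape[-1] - 1)
        frac = j - i0
        i0 = np.minimum(i0, down.shape[-1] - 1)
        out = down[..., i0] * (1 - frac) + down[..., i1] * frac
    return np.moveaxis(out, -1, axis)


def corrupt_anisotropy(v: Volume, severity: int, seed: int, table=None, mode: str = "linear") -> Volume:
    """Wrong-resolution artifact: downsample by an integer factor along one
    random axis (keeping every factor-th slice), then upsample back to the
    original shape (linear by default, floor-nearest optionally)."""
    p = _params("anisotropy", severity, table)
    factor = int(p["factor"])
    if factor <= 1:
        return Volume(data=v.data.copy(), spacing=v.spacing, affine=v.affine)
    rng = _rng(seed)
    axis = int(rng.integers(0, 3))
    n = v.shape[axis]
    factor = min(factor, n)  # clamp: axis shorter than the factor
    down = np.moveaxis(v.data, axis, -1)[..., ::factor]
    down = np.moveaxis(down, -1, axis)
    data = _upsample_axis(down, axis, n, factor, mode)
    return Volume(data=data, spacing=v.spacing, affine=v.affine)


def corrupt_ghosting(v: Volume, severity: int, seed: int, table=None) -> Volume:
    """Motion ghosts: blend attenuated circularly shifted copies along one axis.

    out = (1 − w) v + (w/G) sum_{g=1..G} shift(v, g*Δ) with Δ = round(n/(G+1)).
    """
    p = _params("ghosting", severity, table)
    w, G = p["w"], int(p["ghosts"])
    if w == 0 or G == 0:
        return Volume(data=v.data.copy(), spacing=v.spacing, affine=v.affine)
    rng = _rng(seed)
    axis = int(rng.integers(0, 3))
    delta = max(1, int(round(v.shape[axis] / (G + 1))))
    out = (1 - w) * v.data
    for g in range(1, G + 1):
        out = out + (w / G) * np.roll(v.data, g * delta, axis=axis)
    return Volume(data=out, spacing=v.spacing, affine=v.affine)


def _rigid_transform(data: np.ndarray, rng: np.random.Generator, rot_deg: float, trans_vox: float) -> np.ndarray:
    """Rotate about the volume center around a random axis pair and translate."""
    angle = np.deg2rad(rng.uniform(-rot_deg, rot_deg))
    axes = rng.permutation(3)[:2]
    c, s = np.cos(angle), np.sin(angle)
    R = np.eye(3)
    a0, a1 = int(axes[0]), int(axes[1])
    R[a0, a0], R[a0, a1], R[a1, a0], R[a1, a1] = c, -s, s, c
    t = rng.uniform(-trans_vox, trans_vox, size=3)
    center = (np.array(data.shape) - 1) / 2.0
    # affine_transform: input_coord = R @ output_coord + offset
    offset = center - R @ center - t
    if rot_deg == 0 and trans_vox == 0:
        return data.copy()
    return ndimage.affine_transform(data, R, offset=offset, order=1, mode="nearest")


def corrupt_motion(v: Volume, severity: int, seed: int, table=None) -> Volume:
    """Mid-acquisition motion: k-space segments replaced by transforms of
    rigidly perturbed copies of the volume.

    T rigid perturbations (rotation/translation magnitudes from the severity
    table) yield T+1 k-space segments along one random axis; the first keeps
    the original data, the rest come from the perturbed copies.
    """
    p = _params("motion", severity, table)
    T = int(p["transforms"])
    rng = _rng(seed)
    if T == 0 or (p["rot_deg"] == 0 and p["trans_vox"] == 0):
        return Volume(data=v.data.copy(), spacing=v.spacing, affine=v.affine)
    axis = int(rng.integers(0, 3))
    F = np.fft.fftn(v.data)
    n = v.shape[axis]
    edges = np.linspace(0, n, T + 2).astype(int)
    for t in range(T):
        moved = _rigid_transform(v.data, rng, p["rot_deg"], p["trans_vox"])
        Fm = np.fft.fftn(moved)
        sel = [slice(None)] * 3
        sel[axis] = slice(edges[t + 1], edges[t + 2])
        F[tuple(sel)] = Fm[tuple(sel)]
    data = np.real(np.fft.ifftn(F))
    return Volume(data=data, spacing=v.spacing, affine=v.affine)


_DISPATCH = {
    "local_noise": corrupt_local,
    "elastic": corrupt_elastic,
    "kspace": corrupt_kspace,
    "anisotropy": corrupt_anisotropy,
    "ghosting": corrupt_ghosting,
    "motion": corrupt_motion,
}


def corrupt(v: Volume, spec: CorruptionSpec) -> Volume:
    """Apply the corruption described by a :class:`CorruptionSpec`."""
    return _DISPATCH[spec.kind](v, spec.severity, spec.seed)
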