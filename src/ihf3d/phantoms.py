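"""Synthetic phantom volumes emulating an in-distribution imaging cohort.

Each phantom is an ellipsoidal "body" on a darker background with a few
Gaussian "lesion" blobs and additive Gaussian noise — deliberately simple
anatomy whose purpose is statistical: a stable in-distribution intensity
profile with small per-subject variation (body size jitter, lesion count),
against which controllable distribution shifts can be generated:

- ``intensity_shift``  — adds a constant to the tissue levels (body + blobs,
  not the air background), emulating a scanner/protocol intensity offset;
- ``contrast_change``  — gamma curve on the normalized intensities,
  emulating a contrast/windowing difference;
- ``anatomy_change``   — replaces the ellipsoid with a box-like
  superellipsoid body, emulating a different anatomical region.

Default intensity levels are MRI-like arbitrary units.  All generation is
deterministic under the seed; fixtures derive per-volume seeds from a single
base seed so train/test arms never share one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import MaskVolume, Volume

__all__ = ["PhantomConfig", "ChallengeFixture", "SHIFT_KINDS", "generate_id_phantom", "generate_shifted_phantom", "build_fixture"]

SHIFT_KINDS = ("intensity_shift", "contrast_change", "anatomy_change")


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    background_level: float = 20.0
    body_level: float = 100.0
    blob_count_range: tuple[int, int] = (2, 6)
    blob_intensity: tuple[float, float] = (160.0, 10.0)  # mean, sd
    blob_sigma_range: tuple[float, float] = (1.5, 2.5)  # voxels
    body_jitter: float = 0.02  # relative semi-axis variation
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if not all(n > 0 for n in self.shape) or not all(s > 0 for s in self.spacing):
            raise ValueError("shape and spacing must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ChallengeFixture:
    """Generated train/test arms for one OOD challenge, with ID/OOD labels."""

    train_id: list[Volume]
    test_id: list[Volume]
    test_ood: list[Volume]
    masks: list[MaskVolume]  # blob occupancy for the ID arms (train then test)
    labels: list[str] = field(default_factory=list)


def _body_support(
    shape: tuple[int, int, int], rng: np.random.Generator, jitter: float, exponent: float = 2.0
) -> np.ndarray:
    """Interior of a (super)ellipsoid with jittered size/center; exponent 2 is
    an ellipsoid, larger exponents approach a box."""
    semi = np.array(shape) * 0.35 * rng.uniform(1 - jitter, 1 + jitter, size=3)
    center = np.array(shape) / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    grids = np.indices(shape).astype(np.float64)
    r = sum((np.abs(grids[a] - center[a]) / semi[a]) ** exponent for a in range(3))
    return r <= 1.0


def _phantom(
    config: PhantomConfig,
    seed: int,
    body_level: float,
    blob_mean: float,
    exponent: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    body = _body_support(config.shape, rng, config.body_jitter, exponent=exponent)
    data = np.full(config.shape, config.background_level, dtype=np.float64)
    data[body] = body_level
    mask = np.zeros(config.shape, dtype=bool)

    n_blobs = int(rng.integers(config.blob_count_range[0], config.blob_count_range[1] + 1))
    center = np.array(config.shape) / 2.0
    grids = np.indices(config.shape).astype(np.float64)
    for _ in range(n_blobs):
        # draw blob centers until one lands inside the body
        for _attempt in range(50):
            pos = center + (rng.uniform(-0.25, 0.25, size=3)) * np.array(config.shape)
            if body[tuple(np.round(pos).astype(int))]:
                break
        sigma = rng.uniform(*config.blob_sigma_range)
        amp = rng.normal(blob_mean, config.blob_intensity[1]) - body_level
        r2 = sum((grids[a] - pos[a]) ** 2 for a in range(3))
        blob = amp * np.exp(-r2 / (2 * sigma**2))
        data += np.where(body, blob, 0.0)
        mask |= body & (np.abs(blob) > 0.5 * abs(amp))  # half-maximum support

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=config.shape)
    return data, mask


def generate_id_phantom(config: PhantomConfig, seed: int) -> tuple[Volume, MaskVolume]:
    """One in-distribution phantom plus its lesion-occupancy mask."""
    data, mask = _phantom(config, seed, config.body_level, config.blob_intensity[0])
    return (
        Volume(data=data, spacing=config.spacing),
        MaskVolume(data=mask.astype(np.uint8), spacing=config.spacing),
    )


def generate_shifted_phantom(config: PhantomConfig, shift: str, magnitude: float, seed: int) -> Volume:
    """One phantom from a distribution-shifted arm (see module docstring)."""
    if shift not in SHIFT_KINDS:
        raise ValueError(f"unknown shift kind {shift!r}; choose from {SHIFT_KINDS}")
    if shift == "intensity_shift":
        data, _ = _phantom(config, seed, config.body_level + magnitude, config.blob_intensity[0] + magnitude)
    elif shift == "contrast_change":
        data, _ = _phantom(config, seed, config.body_level, config.blob_intensity[0])
        lo, hi = float(data.min()), float(data.max())
        if hi > lo and magnitude != 1.0:
            data = lo + (hi - lo) * ((data - lo) / (hi - lo)) ** magnitude
    else:  # anatomy_change: box-like body; magnitude sets the superellipsoid exponent
        exponent = magnitude if magnitude > 0 else 4.0
        data, _ = _phantom(config, seed, config.body_level, config.blob_intensity[0], exponent=exponent)
    return Volume(data=data, spacing=config.spacing)


def build_fixture(
    config: PhantomConfig,
    n_train: int,
    n_test_id: int,
    n_test_ood: int,
    shift: str = "intensity_shift",
    magnitude: float | None = None,
    base_seed: int = 0,
) -> ChallengeFixture:
    """Deterministically generate train/test arms for one challenge.

    Per-volume seeds are spawned from ``base_seed`` so the arms are disjoint;
    the default shift magnitude is 3x the phantom noise sd.
    """
    if min(n_train, n_test_id, n_test_ood) <= 0:
        raise ValueError("all counts must be positive")
    if magnitude is None:
        magnitude = 3.0 * config.noise_sd
    seeds = np.random.SeedSequence(base_seed).generate_state(n_train + n_test_id + n_test_ood)
    seeds = [int(s % (2**31)) for s in seeds]
    train, masks = [], []
    for s in seeds[:n_train]:
        v, m = generate_id_phantom(config, s)
        train.append(v)
        masks.append(m)
    test_id = []
    for s in seeds[n_train : n_train + n_test_id]:
        v, m = generate_id_phantom(config, s)
        test_id.append(v)
        masks.append(m)
    test_ood = [generate_shifted_phantom(config, shift, magnitude, s) for s in seeds[n_train + n_test_id :]]
    labels = ["ID"] * (n_train + n_test_id) + ["OOD"] * n_test_ood
    return ChallengeFixture(train_id=train, test_id=test_id, test_ood=test_ood, masks=masks, labels=labels)
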