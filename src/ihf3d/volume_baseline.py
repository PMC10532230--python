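"""Predicted-volume OOD baseline.

A deliberately trivial detector: the only feature is the total physical
volume (mm^3) of a downstream model's binary prediction mask.  A test sample
is outlying if its predicted volume falls in either tail of the
in-distribution volume distribution; with tail mass q split evenly
(q/2 per side) the rule retains roughly 100 − q percent of ID samples.

For ranking-based metrics the two-sided rule is scalarized as the symmetric
deviation of the mid-rank empirical CDF from 1/2, giving a score in
[0, 0.5] where higher means more outlying.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volume_io import MaskVolume

__all__ = [
    "VolumeReference",
    "prediction_volume",
    "fit_volume_reference",
    "volume_score",
    "volume_decision",
    "save_volume_reference",
    "load_volume_reference",
]


@dataclass
class VolumeReference:
    """Sorted in-distribution prediction volumes (mm^3)."""

    id_volumes: np.ndarray

    def __post_init__(self) -> None:
        self.id_volumes = np.sort(np.asarray(self.id_volumes, dtype=np.float64))
        if self.id_volumes.size < 1:
            raise ValueError("reference needs at least one volume")
        if np.any(self.id_volumes < 0):
            raise ValueError("volumes must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.id_volumes.size)


def prediction_volume(mask: MaskVolume) -> float:
    """Total volume of the positive class in mm^3: voxel count times voxel volume."""
    sx, sy, sz = mask.spacing
    return float(np.count_nonzero(mask.data)) * sx * sy * sz


def fit_volume_reference(masks: list[MaskVolume]) -> VolumeReference:
    if not masks:
        raise ValueError("need at least one mask")
    return VolumeReference(id_volumes=[prediction_volume(m) for m in masks])


def volume_score(ref: VolumeReference, vol: float) -> float:
    """Two-sided outlyingness |F̂(vol) − 0.5| under the mid-rank empirical CDF.

    F̂(v) = (#{id < v} + 0.5 * #{id = v}) / n, so the reference median scores 0
    and values beyond either extreme score 0.5.
    """
    below = np.count_nonzero(ref.id_volumes < vol)
    equal = np.count_nonzero(ref.id_volumes == vol)
    f = (below + 0.5 * equal) / ref.n
    return float(abs(f - 0.5))


def volume_decision(ref: VolumeReference, vol: float, q: float = 5.0) -> bool:
    """Flag as outlier if vol is strictly below the q/2-th or strictly above the
    (100 − q/2)-th percentile of the reference volumes (linear-interpolation
    percentiles); retains about 100 − q percent TPR on ID data."""
    if not 0 < q < 100:
        raise ValueError(f"q must be in (0, 100), got {q}")
    lo, hi = np.percentile(ref.id_volumes, [q / 2, 100 - q / 2])
    return bool(vol < lo or vol > hi)


def save_volume_reference(ref: VolumeReference, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"id_volumes": ref.id_volumes.tolist()}))


def load_volume_reference(path: str | Path) -> VolumeReference:
    return VolumeReference(id_volumes=json.loads(Path(path).read_text())["id_volumes"])
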