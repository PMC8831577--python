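"""EAT quantification: fat-window thresholding inside the pericardial sac,
volume integration, and mean fat attenuation.

Fat occupies roughly [-190, -30] HU on CT; a voxel is counted as
epicardial adipose tissue iff it lies inside the sac-interior mask and its
(median-filtered) HU falls in that closed interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from deepfat.preprocess import median_filter_mm
from deepfat.volume_io import CTVolume, MaskVolume

__all__ = [
    "FatWindow",
    "EATResult",
    "threshold_fat",
    "eat_volume_cm3",
    "eat_mean_hu",
    "per_slice_volume",
    "quantify_eat",
]


@dataclass(frozen=True)
class FatWindow:
    """Closed HU interval identifying fat. Both ends inclusive."""

    lo: float = -190.0
    hi: float = -30.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"fat window requires lo < hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class EATResult:
    """EAT mask plus the scalar measurements reported per scan."""

    eat_mask: MaskVolume
    total_volume_cm3: float
    mean_hu: float
    per_slice_volume_cm3: tuple[float, ...]
    scan_id: str = ""

    def to_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "eat_volume_cm3": round(self.total_volume_cm3, 2),
            "eat_mean_hu": round(self.mean_hu, 2),
            "per_slice_volume_cm3": [round(v, 6) for v in self.per_slice_volume_cm3],
        }


def threshold_fat(
    volume: CTVolume, sac_mask: MaskVolume, window: FatWindow = FatWindow()
) -> MaskVolume:
    """Voxel is EAT iff inside the sac and HU in [lo, hi] (closed).

    ``volume`` is expected to be median-filtered already when mirroring the
    clinical protocol; this function applies no filtering itself.
    """
    if volume.voxels.shape != sac_mask.voxels.shape:
        raise ValueError(
            f"volume shape {volume.voxels.shape} != mask shape {sac_mask.voxels.shape}"
        )
    in_window = (volume.voxels >= window.lo) & (volume.voxels <= window.hi)
    eat = (sac_mask.voxels.astype(bool) & in_window).astype(np.uint8)
    return MaskVolume(voxels=eat, spacing=volume.spacing, label="EAT")


def eat_volume_cm3(mask: MaskVolume) -> float:
    """Total mask volume: set-voxel count x voxel volume, in cm^3."""
    return mask.n_voxels_set * mask.voxel_volume_mm3 / 1000.0


def eat_mean_hu(volume: CTVolume, mask: MaskVolume) -> float:
    """Arithmetic mean HU over mask voxels; errors on an empty mask."""
    if volume.voxels.shape != mask.voxels.shape:
        raise ValueError("volume and mask shapes differ")
    sel = mask.voxels.astype(bool)
    if not sel.any():
        raise ValueError("mean HU undefined for an empty mask")
    return float(volume.voxels[sel].mean())


def per_slice_volume(mask: MaskVolume) -> list[float]:
    """Per-axial-slice volumes in cm^3; sums to :func:`eat_volume_cm3`."""
    counts = mask.voxels.reshape(mask.voxels.shape[0], -1).sum(axis=1)
    vv = mask.voxel_volume_mm3 / 1000.0
    return [float(c) * vv for c in counts]


def quantify_eat(
    volume: CTVolume,
    sac_mask: MaskVolume,
    window: FatWindow = FatWindow(),
    median_kernel_mm: float | None = 3.0,
) -> EATResult:
    """Full quantification: median filter, threshold, integrate.

    Mirrors the manual protocol's order: the HU volume is median-filtered
    (3 mm physical kernel by default; pass ``None`` to skip), fat is
    thresholded inside the sac, and volumes/mean HU are computed on the
    filtered volume for consistency with the mask.
    """
    if median_kernel_mm is not None:
        volume = median_filter_mm(volume, kernel_mm=median_kernel_mm)
    eat = threshold_fat(volume, sac_mask, window)
    slices = per_slice_volume(eat)
    total = eat_volume_cm3(eat)
    mean_hu = eat_mean_hu(volume, eat) if eat.n_voxels_set else float("nan")
    return EATResult(
        eat_mask=eat,
        total_volume_cm3=total,
        mean_hu=mean_hu,
        per_slice_volume_cm3=tuple(slices),
        scan_id=volume.scan_id,
    )
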