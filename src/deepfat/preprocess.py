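"""Method-defining preprocessing: HU-attention-window and the bisected
look-ahead slab plan, plus physical-kernel median filtering.

The HU-attention-window maps HU linearly onto 8-bit so pericardial
contrast survives quantization.  The bisect plan splits the heart slices
into a lower and an upper half, presents the lower half bottom-to-middle
and the upper half top-to-middle, and feeds each target slice together
with its two look-ahead neighbours on the side of increasing sac area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from deepfat.volume_io import CTVolume, HeartExtent

__all__ = [
    "WindowSpec",
    "SlabPlan",
    "Slab",
    "hu_window_to_8bit",
    "bisect_plan",
    "sequential_plan",
    "assemble_slab",
    "median_filter_mm",
]


@dataclass(frozen=True)
class WindowSpec:
    """Linear window/level display mapping. Defaults: window 350, level 40 HU."""

    width: float = 350.0
    level: float = 40.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


#: full-range mapping used for the "without HU-attention-window" ablation:
#: the whole 12-bit HU range is squeezed into 8 bits, losing soft-tissue contrast
FULL_RANGE_WINDOW = WindowSpec(width=4096.0, level=1024.0)


@dataclass(frozen=True)
class SlabPlan:
    """Presentation order for per-slice segmentation.

    ``entries`` is an ordered list of ``(k, s)`` where ``k`` is the target
    slice index within the heart extent (0 = bottom) and ``s`` in {+1, -1}
    is the look-ahead direction.
    """

    entries: tuple[tuple[int, int], ...]
    split: int

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def targets(self) -> list[int]:
        return [k for k, _ in self.entries]


@dataclass(frozen=True)
class Slab:
    """Three stacked 8-bit slices (k, k+s, k+2s) forming one network input."""

    channels: np.ndarray  # (3, H, W) uint8
    target: int

    def __post_init__(self) -> None:
        c = np.asarray(self.channels)
        if c.ndim != 3 or c.shape[0] != 3:
            raise ValueError(f"slab channels must be (3, H, W), got {c.shape}")
        object.__setattr__(self, "channels", c.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


def hu_window_to_8bit(
    voxels: np.ndarray | CTVolume, spec: WindowSpec = WindowSpec()
) -> np.ndarray:
    """Map HU to 8-bit with a linear clamp over [level - w/2, level + w/2].

    v8 = round(255 * clamp((HU - lo) / (hi - lo), 0, 1)), round-half-up.
    Monotone non-decreasing in HU; HU at or below ``lo`` -> 0, at or above
    ``hi`` -> 255.
    """
    hu = voxels.voxels if isinstance(voxels, CTVolume) else np.asarray(voxels)
    frac = np.clip((hu - spec.lo) / (spec.hi - spec.lo), 0.0, 1.0)
    # np.round ties to even; the radiology convention is round-half-up
    return np.floor(frac * 255.0 + 0.5).astype(np.uint8)


def bisect_plan(extent: HeartExtent | int) -> SlabPlan:
    """Build the bisected presentation order for ``n`` heart slices.

    Lower half (indices ``0 .. floor(n/2)-1``) is presented ascending with
    step +1; upper half (``n-1`` down to ``floor(n/2)``) descending with
    step -1.  Each half therefore walks toward the middle, where the sac's
    cross-section is largest, so the look-ahead slices always lie on the
    side of non-decreasing sac area.  For odd ``n`` the middle slice joins
    the upper half.
    """
    n = extent if isinstance(extent, int) else extent.n_slices
    if n < 3:
        raise ValueError(f"bisect plan needs >= 3 slices, got {n}")
    split = n // 2
    lower = [(k, +1) for k in range(split)]
    upper = [(k, -1) for k in range(n - 1, split - 1, -1)]
    return SlabPlan(entries=tuple(lower + upper), split=split)


def sequential_plan(extent: HeartExtent | int) -> SlabPlan:
    """Ablation plan: all slices bottom-to-top with step +1 (no bisection)."""
    n = extent if isinstance(extent, int) else extent.n_slices
    if n < 3:
        raise ValueError(f"plan needs >= 3 slices, got {n}")
    return SlabPlan(entries=tuple((k, +1) for k in range(n)), split=n)


def assemble_slab(volume8: np.ndarray, k: int, s: int) -> Slab:
    """Stack slices (k, k+s, k+2s) of an 8-bit heart-extent volume.

    ``volume8`` holds only the heart extent (slice 0 = heart bottom).
    Look-ahead indices may cross the half-way point freely; indices that
    would fall outside the extent are clamped by replicating the nearest
    in-extent slice (possible only near the extent borders).
    """
    n = volume8.shape[0]
    if not 0 <= k < n:
        raise ValueError(f"target slice {k} outside extent of {n} slices")
    if s not in (+1, -1):
        raise ValueError(f"step must be +1 or -1, got {s}")
    idx = [min(max(k + j * s, 0), n - 1) for j in range(3)]
    return Slab(channels=np.stack([volume8[i] for i in idx], axis=0), target=k)


def median_filter_mm(volume: CTVolume, kernel_mm: float = 3.0) -> CTVolume:
    """Rank-median filter with a physical (mm) kernel size.

    The voxel kernel per axis is ``2 * floor(kernel_mm / (2 * spacing)) + 1``
    — the largest odd voxel count whose physical span does not exceed
    ``kernel_mm``.  With 2.5 mm slices and a 3 mm kernel this degenerates
    to an in-plane (single-slice) median.  Edges use nearest-value padding.
    """
    if kernel_mm <= 0:
        raise ValueError("kernel_mm must be > 0")
    row_mm, col_mm, slice_mm = volume.spacing
    size = tuple(
        2 * int(np.floor(kernel_mm / (2.0 * sp))) + 1 for sp in (slice_mm, row_mm, col_mm)
    )
    filtered = ndimage.median_filter(volume.voxels, size=size, mode="nearest")
    return CTVolume(voxels=filtered, spacing=volume.spacing, scan_id=volume.scan_id)


def kernel_voxels(spacing: tuple[float, float, float], kernel_mm: float = 3.0) -> tuple[int, int, int]:
    """Voxel kernel (slices, rows, cols) used by :func:`median_filter_mm`."""
    row_mm, col_mm, slice_mm = spacing
    return tuple(
        2 * int(np.floor(kernel_mm / (2.0 * sp))) + 1 for sp in (slice_mm, row_mm, col_mm)
    )
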