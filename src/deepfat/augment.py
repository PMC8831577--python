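"""Training-set enrichment: blur duplication done once up front, plus
per-epoch random rotation/scale, with exact presentation accounting.

Blur duplication doubles the slice count (each original is followed by a
Gaussian-blurred copy, sigma ~ Uniform(0, 2) pixels, mask untouched).
Every epoch then draws a fresh rotation in (-5, +5) degrees and a scale in
(0.9, 1.1) per item, applied identically to all three slab channels and
nearest-neighbour to the mask, so a run of ``n`` slices over ``e`` epochs
presents ``2 n e`` images to the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from deepfat.preprocess import Slab

__all__ = [
    "AugmentConfig",
    "blur_duplicate",
    "random_geometric",
    "presentation_count",
]


@dataclass(frozen=True)
class AugmentConfig:
    rotation_deg: tuple[float, float] = (-5.0, 5.0)
    scale: tuple[float, float] = (0.9, 1.1)
    blur_sigma: tuple[float, float] = (0.0, 2.0)  # upper bound exclusive
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "scale", "blur_sigma"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} interval must be non-empty, got ({lo}, {hi})")


def blur_duplicate(
    slabs: list[tuple[Slab, np.ndarray]],
    config: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | None = None,
) -> list[tuple[Slab, np.ndarray]]:
    """Duplicate each (slab, mask) pair with a randomly blurred image copy.

    Output length is exactly twice the input length; each original is
    followed by a copy whose channels are Gaussian-blurred with a sigma
    drawn per copy from Uniform[0, 2); the copy's mask is the original's.
    """
    if not slabs:
        raise ValueError("blur_duplicate requires a non-empty slab list")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.blur_sigma
    out: list[tuple[Slab, np.ndarray]] = []
    for slab, mask in slabs:
        out.append((slab, mask))
        sigma = float(rng.uniform(lo, hi))
        if sigma > 0:
            blurred = np.stack(
                [
                    ndimage.gaussian_filter(ch.astype(np.float32), sigma=sigma)
                    for ch in slab.channels
                ]
            )
            blurred = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
        else:
            blurred = slab.channels.copy()
        out.append((Slab(channels=blurred, target=slab.target), mask.copy()))
    return out


def _affine_params(
    shape: tuple[int, int], angle_deg: float, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse affine (matrix, offset) for a rotation+scale about the centre."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    forward = scale * np.array([[c, -s], [s, c]])
    inv = np.linalg.inv(forward)
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    offset = centre - inv @ centre
    return inv, offset


def random_geometric(
    slab: Slab,
    mask: np.ndarray,
    config: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[Slab, np.ndarray]:
    """Apply one random rotation+scale draw to a slab and its mask.

    One angle and one scale are drawn per call and applied identically to
    all three channels (bilinear) and the mask (nearest-neighbour, so it
    stays binary).  Pixels pulled in from outside the frame are filled
    with 0, the 8-bit value of air-range HU after windowing.
    """
    if mask.shape != slab.shape:
        raise ValueError(f"mask shape {mask.shape} != slab shape {slab.shape}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    angle = float(rng.uniform(*config.rotation_deg))
    scale = float(rng.uniform(*config.scale))
    inv, offset = _affine_params(slab.shape, angle, scale)

    channels = np.stack(
        [
            np.clip(
                np.rint(
                    ndimage.affine_transform(
                        ch.astype(np.float32), inv, offset=offset, order=1, cval=0.0
                    )
                ),
                0,
                255,
            ).astype(np.uint8)
            for ch in slab.channels
        ]
    )
    warped_mask = ndimage.affine_transform(
        mask.astype(np.uint8), inv, offset=offset, order=0, cval=0
    ).astype(np.uint8)
    return Slab(channels=channels, target=slab.target), warped_mask


def presentation_count(n_slices: int, epochs: int) -> tuple[int, int]:
    """Exact accounting of images presented to the network.

    Blur duplication doubles the slice count once; per-epoch geometric
    augmentation re-presents every duplicated slice each epoch:
    ``after_dup = 2 * n_slices`` and ``total = after_dup * epochs``.
    """
    if n_slices < 1 or epochs < 1:
        raise ValueError("n_slices and epochs must be >= 1")
    after_dup = 2 * n_slices
    return after_dup, after_dup * epochs
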