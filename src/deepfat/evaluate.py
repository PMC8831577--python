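"""Segmentation-overlap metrics and agreement analytics.

Overlap: Dice = 2|A∩B| / (|A| + |B|) and IOU (Jaccard) = |A∩B| / |A∪B|,
computed per axial slice and per whole volume.  Agreement between paired
volume measurements: Bland–Altman bias and 1.96·sd limits of agreement,
origin-constrained regression y = mx with Pearson R, percent error, and
the paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from deepfat.volume_io import HeartExtent, MaskVolume

__all__ = [
    "AgreementStats",
    "OriginFit",
    "DiceReport",
    "dice",
    "iou",
    "dice_report",
    "quartile_groups",
    "bland_altman",
    "origin_fit",
    "percent_error",
    "percent_error_summary",
    "paired_t",
]


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman summary of paired differences (test - reference)."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class OriginFit:
    """Least-squares fit of y = mx plus the Pearson correlation of (x, y)."""

    slope: float
    r: float
    p: float


@dataclass(frozen=True)
class DiceReport:
    volume_dice: float
    per_slice_dice: tuple[float, ...]
    slice_mean: float
    slice_sd: float


def _as_binary(a) -> np.ndarray:
    arr = np.asarray(a)
    return arr.astype(bool)


def dice(A, B) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); both-empty convention -> 1."""
    a, b = _as_binary(A), _as_binary(B)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def iou(A, B) -> float:
    """Jaccard index |A∩B| / (|A|+|B|-|A∩B|); both-empty -> 1."""
    a, b = _as_binary(A), _as_binary(B)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    inter = int((a & b).sum())
    union = int(a.sum()) + int(b.sum()) - inter
    if union == 0:
        return 1.0
    return inter / union


def dice_report(
    pred: MaskVolume, truth: MaskVolume, extent: HeartExtent | None = None
) -> DiceReport:
    """Volume Dice over in-extent voxels plus per-slice Dice with mean ± sd.

    Slices where prediction and truth are both empty score 1 by convention
    (the empty planes above and below the fat agree perfectly); they are
    included in the per-slice list so callers can exclude them explicitly.
    """
    p, t = pred.voxels, truth.voxels
    if p.shape != t.shape:
        raise ValueError("pred/truth masks misaligned")
    if extent is not None:
        p = p[extent.bottom : extent.top + 1]
        t = t[extent.bottom : extent.top + 1]
    per_slice = tuple(dice(p[i], t[i]) for i in range(p.shape[0]))
    arr = np.asarray(per_slice)
    return DiceReport(
        volume_dice=dice(p, t),
        per_slice_dice=per_slice,
        slice_mean=float(arr.mean()),
        slice_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    )


def quartile_groups(n_slices: int) -> list[list[int]]:
    """Split slice indices 0..n-1 into four contiguous bottom-to-top groups.

    Sizes are as equal as possible; when ``n mod 4 = r`` the first ``r``
    groups receive the extra slice.
    """
    if n_slices < 4:
        raise ValueError(f"quartile grouping needs >= 4 slices, got {n_slices}")
    base, r = divmod(n_slices, 4)
    groups, start = [], 0
    for g in range(4):
        size = base + (1 if g < r else 0)
        groups.append(list(range(start, start + size)))
        start += size
    return groups


def bland_altman(reference, test) -> AgreementStats:
    """Bland–Altman agreement of paired measurements.

    Differences are ``test - reference``; bias is their mean, sd uses the
    n-1 denominator, and the limits of agreement are bias ± 1.96 sd.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError("length mismatch")
    n = ref.size
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = tst - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=n
    )


def origin_fit(x, y) -> OriginFit:
    """Fit y = mx through the origin; report slope, Pearson R and its p.

    m = Σ x_i y_i / Σ x_i²; R and the two-sided p come from the ordinary
    Pearson correlation of (x, y) (t transform, n-2 df).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length inputs with >= 2 points")
    sxx = float((x * x).sum())
    if sxx == 0:
        raise ValueError("degenerate x: all zero")
    m = float((x * y).sum()) / sxx
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        # Pearson r undefined for a constant sequence
        return OriginFit(slope=m, r=float("nan"), p=float("nan"))
    r, p = stats.pearsonr(x, y)
    return OriginFit(slope=m, r=float(r), p=float(p))


def percent_error(auto: float, manual: float) -> float:
    """Signed percent error 100 (auto - manual) / manual; manual must be > 0."""
    if manual <= 0:
        raise ValueError("manual reference volume must be > 0")
    return 100.0 * (auto - manual) / manual


def percent_error_summary(auto, manual) -> tuple[float, float]:
    """Cohort mean ± sd (n-1) of per-scan percent errors."""
    errs = np.array([percent_error(a, m) for a, m in zip(auto, manual, strict=True)])
    sd = float(errs.std(ddof=1)) if errs.size > 1 else 0.0
    return float(errs.mean()), sd


def paired_t(x, y) -> tuple[float, float]:
    """Paired two-sided t-test on differences x_i - y_i.

    Raises on degenerate (zero-variance) differences, where t is infinite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length inputs with >= 2 points")
    d = x - y
    if float(d.std(ddof=1)) == 0.0:
        if float(d.mean()) == 0.0:
            return 0.0, 1.0  # identical pairs: no evidence of a difference
        raise ValueError("zero-variance nonzero differences: t is unbounded")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
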