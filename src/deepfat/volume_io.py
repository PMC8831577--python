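"""CT volume and mask I/O with a fixed anatomical slice convention.

All in-memory volumes are Hounsfield units (float32) indexed ``[z, row, col]``
with slice index 0 the most inferior slice and the index increasing toward
the head.  CT series are read from DICOM; binary masks are exchanged as
NIfTI (uint8, values {0, 1}) whose affine carries the voxel spacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "CTVolume",
    "HeartExtent",
    "MaskVolume",
    "load_ct_series",
    "save_mask",
    "load_mask",
    "crop_to_extent",
]

#: tolerated relative jitter in inter-slice spacing before a series is rejected
SLICE_SPACING_TOL = 0.01


@dataclass(frozen=True)
class CTVolume:
    """A 3D HU grid with physical spacing.

    Attributes
    ----------
    voxels:
        float32 array, shape ``(n_slices, n_rows, n_cols)``, Hounsfield units.
    spacing:
        ``(row_mm, col_mm, slice_mm)`` voxel spacing, all > 0.
    scan_id:
        Opaque identifier carried through the pipeline.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    scan_id: str = ""
    #: index 0 = most inferior slice, increasing superiorly
    slice_order: str = field(default="inferior-to-superior", repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float32)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError(f"voxels must be 3D with >= 1 slice, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("HU values must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        r, c, z = self.spacing
        return r * c * z


@dataclass(frozen=True)
class HeartExtent:
    """Inclusive slice range covering the heart, chosen by an operator."""

    bottom: int
    top: int

    def __post_init__(self) -> None:
        if self.bottom < 0 or self.top < self.bottom:
            raise ValueError(f"invalid extent ({self.bottom}, {self.top})")
        if self.n_slices < 3:
            raise ValueError(
                f"heart extent must span >= 3 slices, got {self.n_slices}"
            )

    @property
    def n_slices(self) -> int:
        return self.top - self.bottom + 1

    def validate_for(self, volume: CTVolume) -> None:
        if self.top >= volume.n_slices:
            raise ValueError(
                f"extent top {self.top} outside volume with {volume.n_slices} slices"
            )


@dataclass(frozen=True)
class MaskVolume:
    """Binary mask aligned voxel-for-voxel with a parent :class:`CTVolume`.

    ``label`` tags the mask's role: ``"sac-interior"`` (pericardial-sac
    interior) or ``"EAT"`` (epicardial adipose tissue).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label: str = "sac-interior"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
        object.__setattr__(self, "voxels", v.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_voxels_set(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        r, c, z = self.spacing
        return r * c * z


def load_ct_series(directory: str | os.PathLike) -> CTVolume:
    """Read one axial CT series from a directory of DICOM files.

    Slices are sorted by the z component of ImagePositionPatient
    (inferior first) regardless of file order, and stored values are
    rescaled to HU with the slope/intercept tags.

    Raises
    ------
    ValueError
        If the directory mixes series, required tags are missing, or the
        inter-slice spacing is non-uniform beyond 1%.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")

    datasets = [pydicom.dcmread(str(p)) for p in files]

    uids = {ds.get("SeriesInstanceUID") for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"directory contains {len(uids)} series, expected exactly 1")

    for ds in datasets:
        if "ImagePositionPatient" not in ds:
            raise ValueError("missing ImagePositionPatient tag")
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError("missing rescale slope/intercept tags")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))

    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise ValueError("duplicate or non-increasing slice positions")
        mean_dz = float(dz.mean())
        if np.max(np.abs(dz - mean_dz)) > SLICE_SPACING_TOL * mean_dz:
            raise ValueError(
                f"inter-slice spacing non-uniform beyond {SLICE_SPACING_TOL:.0%}"
            )
        slice_mm = mean_dz
    else:
        slice_mm = float(datasets[0].get("SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        hu = ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append(hu)
    voxels = np.stack(slices, axis=0)

    row_mm, col_mm = (float(x) for x in datasets[0].PixelSpacing)
    scan_id = str(datasets[0].get("SeriesInstanceUID", directory.name))
    return CTVolume(voxels=voxels, spacing=(row_mm, col_mm, slice_mm), scan_id=scan_id)


def save_mask(mask: MaskVolume, path: str | os.PathLike) -> None:
    """Write a binary mask as NIfTI (uint8, affine carrying spacing).

    The on-disk array is transposed to NIfTI's ``[x, y, z]`` order so the
    affine spacing maps (col, row, slice) -> mm.
    """
    r, c, z = mask.spacing
    affine = np.diag([c, r, z, 1.0])
    data = np.ascontiguousarray(mask.voxels.transpose(2, 1, 0).astype(np.uint8))
    img = nib.Nifti1Image(data, affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def load_mask(
    path: str | os.PathLike, parent: CTVolume, label: str = "sac-interior"
) -> MaskVolume:
    """Read a NIfTI mask and align it to ``parent``.

    Raises
    ------
    ValueError
        On shape mismatch with the parent volume or non-binary values.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxels = data.transpose(2, 1, 0)
    if voxels.shape != parent.voxels.shape:
        raise ValueError(
            f"mask shape {voxels.shape} does not match parent {parent.voxels.shape}"
        )
    uniq = np.unique(voxels)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"mask file contains non-binary values: {uniq[:10]}")
    return MaskVolume(voxels=voxels, spacing=parent.spacing, label=label)


def crop_to_extent(volume: CTVolume, extent: HeartExtent) -> CTVolume:
    """Restrict a volume to the operator-chosen heart slices.

    Slice 0 of the output is slice ``extent.bottom`` of the input; spacing
    and the in-plane grid are unchanged.
    """
    extent.validate_for(volume)
    return CTVolume(
        voxels=volume.voxels[extent.bottom : extent.top + 1],
        spacing=volume.spacing,
        scan_id=volume.scan_id,
    )
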