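"""Synthetic non-contrast cardiac CT phantoms with analytic ground truth.

Each phantom is a stack of axial slices holding a simplified thorax: an
elliptical body of soft tissue on air, two lung fields, and a heart whose
pericardial-sac cross-section grows from the heart bottom to the middle
slice and shrinks toward the top (an ellipsoidal radius profile).  The sac
interior holds blood/myocardium-range tissue plus an inner annulus of
epicardial fat against the thin pericardial wall; paracardial fat lies
just outside the wall so that fat-window thresholding is only correct when
gated by the sac mask.  Compartment HU values are chosen so that, at zero
noise, every EAT voxel lies strictly inside the fat window [-190, -30] HU
and every non-EAT sac-interior voxel lies outside it.  The fat/non-fat
compartment map is additionally regularized into a root signal of the
3 mm rank-median filter (no voxel's kernel neighbourhood holds a majority
of the opposite phase), so fat thresholding against the true sac mask
recovers the EAT mask voxel-exactly even after median filtering.

All HU values are integer-valued (as scanner output is) so a phantom
written as a DICOM series round-trips bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pydicom
from scipy import ndimage
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from deepfat.volume_io import CTVolume, HeartExtent, MaskVolume, save_mask

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_cohort",
           "write_dicom_series"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue model of one synthetic scan.

    Defaults give a 64x64 in-plane grid at calcium-score-like spacing
    (0.7 x 0.7 x 2.5 mm) with 24 heart slices plus padding above and below.
    """

    shape_xy: int = 64
    spacing: tuple[float, float, float] = (0.7, 0.7, 2.5)  # (row, col, slice) mm
    n_heart_slices: int = 24
    n_pad_slices: int = 4  # lung/soft-tissue slices below and above the heart
    r_max_mm: float = 14.0  # sac-interior radius at the middle slice
    wall_mm: float = 1.4  # pericardial wall thickness
    paracardial_mm: float = 3.0  # paracardial fat ring outside the wall
    eat_fraction: float = 0.25  # target EAT share of the sac interior
    #: EAT annulus never thinner than this (keeps median-filtered fat voxels
    #: inside the fat window at zero noise)
    eat_min_thickness_mm: float = 2.1
    #: slices whose sac radius falls below this carry no EAT
    eat_min_radius_mm: float = 6.0
    noise_sd: float = 0.0  # additive Gaussian HU noise
    centre_offset_px: tuple[float, float] = (0.0, 0.0)
    # compartment HU means
    hu_blood: float = 40.0
    hu_wall: float = 20.0
    hu_eat: float = -100.0
    hu_eat_sd: float = 20.0  # per-voxel fat texture, clipped to eat_hu_range
    eat_hu_range: tuple[float, float] = (-180.0, -40.0)
    hu_paracardial: float = -90.0
    hu_soft: float = 30.0
    hu_lung: float = -800.0
    hu_air: float = -1000.0

    def __post_init__(self) -> None:
        if self.n_heart_slices < 3:
            raise ValueError("phantom needs >= 3 heart slices")
        if self.wall_mm < min(self.spacing[:2]):
            raise ValueError("pericardial wall must be at least one voxel thick")
        half_frame_mm = self.shape_xy * min(self.spacing[:2]) / 2.0
        if self.r_max_mm + self.wall_mm + self.paracardial_mm >= half_frame_mm:
            raise ValueError("sac + wall + paracardial ring exceed the frame")
        lo, hi = self.eat_hu_range
        if not (-190.0 < lo < hi < -30.0):
            raise ValueError("EAT HU range must lie strictly inside [-190, -30]")


@dataclass(frozen=True)
class Phantom:
    """A generated scan with its analytic ground truth."""

    ct: CTVolume
    sac: MaskVolume  # pericardial-sac interior
    eat: MaskVolume  # epicardial fat (subset of sac)
    extent: HeartExtent
    truth_eat_cm3: float
    truth_sac_cm3: float
    spec: PhantomSpec
    seed: int


def _radius_profile(spec: PhantomSpec) -> np.ndarray:
    """Sac-interior radius (mm) per heart slice: unimodal, max at the middle."""
    n = spec.n_heart_slices
    z = np.arange(n, dtype=float)
    z_mid = (n - 1) / 2.0
    h = z_mid + 1.5  # keeps the end slices open with a usable radius
    return spec.r_max_mm * np.sqrt(np.clip(1.0 - ((z - z_mid) / h) ** 2, 0.0, None))


def _regularize_to_median_root(
    eat: np.ndarray, para: np.ndarray, interior: np.ndarray, spec: PhantomSpec
) -> np.ndarray:
    """Make the in-sac fat/non-fat map invariant under the rank-median filter.

    Every fat-compartment HU lies below every non-fat HU in the sac's
    surroundings, so the median filter classifies each voxel by the
    majority phase of its kernel neighbourhood.  A geometric annulus
    leaves knife-edge voxels whose neighbourhood holds a majority of the
    opposite phase (curvature and discretization ties); those voxels are
    re-assigned by iterating the majority rule over sac-interior voxels
    until the map is a root signal of the filter.  Converges in a few
    passes; the result keeps EAT ⊆ sac interior.
    """
    from deepfat.preprocess import kernel_voxels

    size = kernel_voxels(spec.spacing)
    kernel = np.ones(size, dtype=np.int32)
    majority = int(np.prod(size)) // 2 + 1
    for _ in range(50):
        fat = eat | para
        counts = ndimage.convolve(fat.astype(np.int32), kernel, mode="nearest")
        new_eat = interior & (counts >= majority)
        if np.array_equal(new_eat, eat):
            return eat
        eat = new_eat
    raise RuntimeError("median-root regularization did not converge")


def generate_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0) -> Phantom:
    """Assemble the compartment model and return scan + ground truth.

    The truth EAT volume is the voxel count of the EAT mask times the
    voxel volume (the same integration the pipeline reports), so recovery
    comparisons are exact rather than continuum approximations.
    """
    rng = np.random.default_rng(seed)
    n_xy = spec.shape_xy
    row_mm, col_mm, _ = spec.spacing
    n_total = spec.n_heart_slices + 2 * spec.n_pad_slices

    cy = (n_xy - 1) / 2.0 + spec.centre_offset_px[0]
    cx = (n_xy - 1) / 2.0 + spec.centre_offset_px[1]
    yy, xx = np.mgrid[0:n_xy, 0:n_xy]
    d_mm = np.hypot((yy - cy) * row_mm, (xx - cx) * col_mm)

    # thorax background shared by every slice: air, body ellipse, two lungs
    body = (
        ((yy - (n_xy - 1) / 2.0) / (0.48 * n_xy)) ** 2
        + ((xx - (n_xy - 1) / 2.0) / (0.48 * n_xy)) ** 2
    ) <= 1.0
    lungs = np.zeros((n_xy, n_xy), dtype=bool)
    for lx in (0.22 * n_xy, 0.78 * n_xy):
        lungs |= (
            ((yy - 0.42 * n_xy) / (0.16 * n_xy)) ** 2
            + ((xx - lx) / (0.11 * n_xy)) ** 2
        ) <= 1.0
    background = np.full((n_xy, n_xy), spec.hu_air, dtype=np.float32)
    background[body] = spec.hu_soft
    background[lungs & body] = spec.hu_lung

    radii = _radius_profile(spec)
    voxels = np.repeat(background[None], n_total, axis=0).copy()
    interior = np.zeros((n_total, n_xy, n_xy), dtype=bool)
    wall = np.zeros_like(interior)
    para = np.zeros_like(interior)
    eat = np.zeros_like(interior)

    for i, r in enumerate(radii):
        z = spec.n_pad_slices + i
        interior[z] = d_mm < r
        wall[z] = (d_mm >= r) & (d_mm < r + spec.wall_mm)
        para[z] = (
            (d_mm >= r + spec.wall_mm)
            & (d_mm < r + spec.wall_mm + spec.paracardial_mm)
            & body
        )
        if r >= spec.eat_min_radius_mm:
            thickness = max(r * (1.0 - np.sqrt(1.0 - spec.eat_fraction)),
                            spec.eat_min_thickness_mm)
            eat[z] = interior[z] & (d_mm >= r - thickness)

    eat = _regularize_to_median_root(eat, para, interior, spec)

    lo, hi = spec.eat_hu_range
    voxels[para] = spec.hu_paracardial
    voxels[wall] = spec.hu_wall
    voxels[interior] = spec.hu_blood
    voxels[eat] = np.clip(
        rng.normal(spec.hu_eat, spec.hu_eat_sd, size=int(eat.sum())), lo, hi
    )
    sac = interior.astype(np.uint8)

    if spec.noise_sd > 0:
        voxels += rng.normal(0.0, spec.noise_sd, size=voxels.shape)
    # scanners emit integer HU on a 12-bit scale
    voxels = np.clip(np.rint(voxels), -1024, 3071).astype(np.float32)

    ct = CTVolume(voxels=voxels, spacing=spec.spacing, scan_id=f"phantom-{seed}")
    sac_mask = MaskVolume(voxels=sac, spacing=spec.spacing, label="sac-interior")
    eat_mask = MaskVolume(voxels=eat, spacing=spec.spacing, label="EAT")
    extent = HeartExtent(
        bottom=spec.n_pad_slices,
        top=spec.n_pad_slices + spec.n_heart_slices - 1,
    )
    vv = np.prod(spec.spacing) / 1000.0
    return Phantom(
        ct=ct,
        sac=sac_mask,
        eat=eat_mask,
        extent=extent,
        truth_eat_cm3=float(eat_mask.n_voxels_set * vv),
        truth_sac_cm3=float(sac_mask.n_voxels_set * vv),
        spec=spec,
        seed=seed,
    )


def generate_cohort(
    n: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    r_max_range_mm: tuple[float, float] = (10.0, 15.0),
    eat_fraction_range: tuple[float, float] = (0.15, 0.35),
    noise_sd_range: tuple[float, float] = (5.0, 15.0),
    centre_jitter_px: float = 3.0,
) -> list[Phantom]:
    """Generate a reproducible cohort with per-phantom randomized anatomy.

    Sac size, EAT fraction, noise level and heart position vary across the
    cohort to emulate patient-to-patient variation in a calcium-score
    population.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    for name, (lo, hi) in (
        ("r_max_range_mm", r_max_range_mm),
        ("eat_fraction_range", eat_fraction_range),
        ("noise_sd_range", noise_sd_range),
    ):
        if lo > hi:
            raise ValueError(f"empty range for {name}")
    rng = np.random.default_rng(seed)
    phantoms = []
    for i in range(n):
        spec = replace(
            base_spec,
            r_max_mm=float(rng.uniform(*r_max_range_mm)),
            eat_fraction=float(rng.uniform(*eat_fraction_range)),
            noise_sd=float(rng.uniform(*noise_sd_range)),
            centre_offset_px=(
                float(rng.uniform(-centre_jitter_px, centre_jitter_px)),
                float(rng.uniform(-centre_jitter_px, centre_jitter_px)),
            ),
        )
        phantoms.append(generate_phantom(spec, seed=int(rng.integers(0, 2**31 - 1))))
    return phantoms


def write_dicom_series(ct: CTVolume, directory: str | os.PathLike) -> None:
    """Write a CTVolume as an axial DICOM series (one file per slice).

    HU values must be integral; they are stored with slope 1 and intercept
    -1024 so a reload through :func:`deepfat.volume_io.load_ct_series`
    reproduces the grid bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not np.allclose(ct.voxels, np.rint(ct.voxels)):
        raise ValueError("DICOM export requires integer HU values")
    intercept = -1024.0
    stored = (ct.voxels - intercept).astype(np.int16)
    if stored.min() < 0:
        raise ValueError("HU below -1024 not representable with this intercept")
    series_uid = generate_uid()
    row_mm, col_mm, slice_mm = ct.spacing
    for i in range(ct.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = series_uid  # single-study synthetic scan
        ds.PatientName = ct.scan_id or "PHANTOM"
        ds.PatientID = ct.scan_id or "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * slice_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [row_mm, col_mm]
        ds.SliceThickness = slice_mm
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = ct.voxels.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[i].tobytes()
        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)


def export_phantom(phantom: Phantom, directory: str | os.PathLike) -> dict:
    """Write a phantom as DICOM series + truth NIfTI masks; return file map."""
    directory = Path(directory)
    series_dir = directory / "series"
    write_dicom_series(phantom.ct, series_dir)
    sac_path = directory / "sac_interior.nii.gz"
    eat_path = directory / "eat.nii.gz"
    save_mask(phantom.sac, sac_path)
    save_mask(phantom.eat, eat_path)
    return {
        "series": str(series_dir),
        "sac": str(sac_path),
        "eat": str(eat_path),
        "extent": (phantom.extent.bottom, phantom.extent.top),
        "truth_eat_cm3": phantom.truth_eat_cm3,
        "truth_sac_cm3": phantom.truth_sac_cm3,
    }
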