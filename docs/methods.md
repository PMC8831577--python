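# Methods

## Problem and pipeline

Epicardial adipose tissue (EAT) is the fat enclosed by the pericardial
sac.  On non-contrast CT calcium score scans (≈2.5 mm slices, no contrast
agent) the sac is a thin, faint membrane, so the pipeline segments the
*region inside the sac* rather than the contour itself, then identifies
EAT by HU thresholding within that region.  The stages are: operator-chosen
heart extent → HU-attention-window → bisected look-ahead slab sequencing →
per-slice semantic segmentation → 3 mm median filtering → fat-window
thresholding → volume/attenuation quantification and agreement evaluation.

## Coordinate and data conventions

Volumes are float32 HU grids indexed `[slice, row, col]`, slice 0 the most
inferior, index increasing toward the head.  This makes the bisect step
directions unambiguous: "bottom-to-middle" is ascending index, with
look-ahead step +1; "top-to-middle" is descending, step −1.  DICOM series
are sorted by the z component of ImagePositionPatient regardless of file
order; inter-slice spacing jitter beyond 1% is a hard error (silent
spacing errors corrupt volumes).  HU is never re-quantized on disk: masks
travel as NIfTI uint8 {0,1} with the spacing in the affine.

## HU-attention-window

`v8 = round(255 · clamp((HU − lo)/(hi − lo), 0, 1))`, round-half-up, with
window/level 350/40 HU (`lo = −135`, `hi = +215`).  The mapping is the
standard radiology display convention: linear between the window edges,
clamped outside.  Round-half-up (rather than banker's rounding) keeps the
map monotone with a fixed tie direction; level 40 maps to 128
(127.5 rounded up).  The "without window" ablation squeezes the full
12-bit range (window 4096/level 1024) into 8 bits instead, which is what
an unwindowed pipeline would implicitly do.

## Bisect sequencing

With `n` heart slices, the lower half is indices `0 .. ⌊n/2⌋−1` ascending
(step +1) and the upper half `n−1` down to `⌊n/2⌋` (step −1); for odd `n`
the middle slice joins the upper half — the halves are exactly equal only
for even `n`, and the extra slice sits adjacent to the middle where either
direction is nearly symmetric.  Look-ahead slices may cross the midline
(the physical slices exist; discarding them would waste context);
replication clamping applies only at the extent borders.  Slabs are
3-channel 8-bit stacks `(k, k+s, k+2s)`, all channels windowed with the
same spec, no per-channel normalization.

## Median filtering with a physical kernel

The voxel kernel per axis is `2·⌊kernel_mm/(2·spacing_ax)⌋ + 1`: the
largest odd voxel count whose centre-to-edge reach stays within half the
physical kernel.  At 0.7 × 0.7 × 2.5 mm and a 3 mm kernel this is 5 × 5 × 1
— an in-plane-only median, which the run logs state explicitly.  Edges use
nearest-value padding.  The network sees *unfiltered* windowed data;
filtering applies only before fat thresholding, mirroring the manual
protocol where noise reduction precedes thresholding.  Mean fat HU is
computed on the filtered volume for consistency with the mask derived
from it.

## Training protocol

Soft Dice loss `1 − (2Σpt + ε)/(Σp + Σt + ε)`, ε = 1e-6 — insensitive to
foreground prevalence, which matters because sac interiors occupy a small
fraction of each slice.  Adam at a constant lr 1e-3 (only the initial rate
is part of the protocol), batch 20, at most 30 epochs.  The training set
is doubled once up front by blur duplication (each slab copied with a
Gaussian blur, σ ~ Uniform[0, 2) pixels, drawn per copy; masks untouched);
every epoch then draws a fresh rotation in (−5°, +5°) and scale in
(0.9, 1.1) per item, applied bilinearly to the channels and
nearest-neighbour to the mask (which therefore stays binary).  Out-of-frame
pixels are filled with 0, the 8-bit value of air after windowing.  This
gives the accounting `2n` slabs per epoch and `2n·epochs` total
presentations.  Validation (mean slice Dice of binarized predictions on
unaugmented slabs) runs each epoch; training stops when its absolute
change between consecutive epochs falls below 1e-5, read as
`|D(e) − D(e−1)|`, the simplest interpretation, logged so alternatives are
auditable.  Probabilistic outputs binarize at 0.5.

## The reference segmenter

The production-scale backbone is deliberately a pluggable contract — large
pretrained semantic-segmentation networks are not this package's
contribution.  The shipped reference model is a ~10k-parameter
encoder–decoder with skip connections (channels 8/16/32 down, 8/4 up,
nearest-neighbour upsampling, sigmoid head) written directly on numpy:
3×3 same-padding convolutions run as nine full-grid BLAS matmuls with
shift-accumulate, with hand-written backward passes verified against a
finite-difference check and scipy correlation.  It trains on one CPU in a
few minutes at 64×64 and exists to exercise the full training and
inference protocol end-to-end, not to compete with pretrained backbones.

## Phantoms

Each phantom is a simplified thorax: elliptical soft-tissue body (+30 HU)
on air, two lung fields (−800 HU), and a heart whose sac-interior radius
follows an ellipsoidal profile `r(z) = r_max·√(1 − ((z − z_mid)/h)²)` —
unimodal with its maximum at the middle slice, which is exactly the
geometry the bisect sequencing assumes.  The sac interior holds
blood-range tissue (+40 HU) with an inner annulus of epicardial fat
against the 1.4 mm wall (+20 HU); fat voxels draw from a clipped normal
(mean −100, sd 20, clipped to [−180, −40] HU — a ≥ 10 HU guard band inside
the fat window).  Paracardial fat (−90 HU) lies just outside the wall so
fat thresholding is only correct when gated by the sac mask.  Defaults:
64×64 in-plane at 0.7 × 0.7 × 2.5 mm, 24 heart slices plus 4 padding
slices of lung/soft tissue on each side so heart-extent selection is
meaningful.  Cohorts randomize sac radius (10–15 mm), EAT fraction
(0.15–0.35), noise sd (5–15 HU, the low-dose CT range) and heart position
(±3 px).  All HU values are integers (as scanner output is), so DICOM
export round-trips bit-exactly.

**Median-root regularization.**  Every fat-compartment HU lies below every
non-fat HU in the sac's surroundings, so the 5×5 rank median classifies a
voxel by the majority phase of its neighbourhood.  A purely geometric
annulus leaves knife-edge voxels whose neighbourhood holds an
opposite-phase majority (curvature and discretization ties), which would
flip under filtering.  The generator therefore iterates the majority rule
over sac-interior voxels until the fat/non-fat map is a *root signal* of
the median filter (converges in a few passes).  This makes the noise-free
invariant exact by construction: thresholding the median-filtered volume
against the true sac mask reproduces the EAT mask voxel-exactly.  Truth
volumes are voxel counts × voxel volume — the same integral the pipeline
reports — so recovery comparisons are exact rather than continuum
approximations.

**What the phantoms do not model:** cardiac chambers and vessels, calcium
lesions, motion artifacts, beam hardening, anisotropic noise texture, and
the irregular, partial-volume-blurred pericardium of real scans.  Passing
phantom tests therefore demonstrates that the pipeline's mechanics
(sequencing, windowing, training loop, thresholding, metrics) are correct,
not that the reference segmenter would reach clinical accuracy on real
calcium score images.

## Evaluation conventions

Dice and IOU use the both-empty = 1 convention (empty slices above and
below the fat agree perfectly); per-slice values are reported individually
so callers can exclude empty slices from summaries.  Slice-Dice summaries
are per-scan means with cohort mean ± sd.  Bland–Altman differences are
automated − manual, sd uses the n−1 denominator, LOA = bias ± 1.96·sd.
Quartile slice groups are contiguous bottom-to-top with remainders
assigned to the earliest groups.  The origin-constrained slope is
`m = Σxy/Σx²`; R and its two-sided p come from the ordinary Pearson
correlation (t transform, n−2 df).  Paired t on identical sequences
returns (0, 1); zero-variance nonzero differences are a degeneracy error.

## Problem sizes

The shipped experiments use 64×64 phantoms: training cohorts of 20 scans
(16 fit + 4 validation, mirroring the 40/10 split of a 50-scan training
set at 40% scale) with 8 held-out test scans, ~480 slabs per epoch before
blur duplication.  These sizes give stable held-out Dice while keeping a
full two-arm (bisect vs. sequential) training comparison to a few minutes
on a single CPU core.

## Known limitations

- The reference segmenter is intentionally small; its absolute Dice on
  real data would be far below a pretrained backbone's.
- The heart extent is a manual input by design; no automatic heart-slice
  classifier is provided.
- No registration, resampling, multi-series handling, or contrast-CTA
  support; one axial series per directory.
- Quantification reports total volume, per-slice volumes and mean HU only;
  no radiomic texture features.
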