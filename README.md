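# deepfat

Automatic segmentation and quantification of **epicardial adipose tissue
(EAT)** on non-contrast, low-dose CT calcium score volumes.

EAT — the fat enclosed by the pericardial sac — is an established marker of
coronary risk, but measuring it by hand is slow and reader-dependent:
calcium score scans are thick-sliced (~2.5 mm), unenhanced, and the
pericardium is a thin, low-contrast membrane.  `deepfat` implements a
per-slice semantic-segmentation pipeline around two method-defining
preprocessing steps, plus the full quantification and agreement-evaluation
stack, and a synthetic phantom generator so every stage is testable without
clinical data.

## The method

1. **HU-attention-window.**  Hounsfield units are mapped to 8-bit with a
   linear window/level of 350/40 HU:
   `v8 = round(255 · clamp((HU − lo)/(hi − lo), 0, 1))` with
   `lo = level − width/2 = −135`, `hi = +215`.  This preserves pericardial
   contrast through 8-bit quantization.
2. **Bisected look-ahead slab sequencing ("bisect").**  The operator marks
   the heart's bottom and top slices.  The heart is split into two halves:
   the lower half is presented bottom-to-middle, the upper half
   top-to-middle, so the sac's cross-sectional area is non-decreasing along
   each presented sequence.  Each target slice *k* is stacked with its two
   look-ahead neighbours *(k+s, k+2s)*, *s = ±1*, into a 3-channel slab.
3. **Per-slice segmentation.**  A pluggable `SliceSegmenter` maps each slab
   to a binary mask of the pericardial-sac interior on slice *k*.  The
   package ships a ~10k-parameter CPU-trainable encoder–decoder reference
   model (`TinyUNet`) and an oracle test double; heavyweight pretrained
   backbones can be adapted behind the same contract.  Training follows the
   clinical protocol: soft Dice loss, Adam at lr 1e-3, batch 20, ≤ 30
   epochs, early stop when the validation Dice changes by < 1e-5, blur
   duplication of the training set and fresh random rotation (±5°) and
   scaling (0.9–1.1) each epoch.
4. **Quantification.**  The HU volume is median-filtered with a 3 mm
   physical kernel, and sac-interior voxels inside the closed fat window
   **[−190, −30] HU** are counted as EAT: total volume (cm³), mean fat HU,
   and per-slice volumes.
5. **Evaluation.**  Dice `2|A∩B|/(|A|+|B|)` and IOU `|A∩B|/|A∪B|` per
   slice and per volume, quartile slice grouping, Bland–Altman bias with
   1.96·sd limits of agreement, origin-constrained regression `y = mx`
   with Pearson R, percent error, and the paired t-test.

## A worked example

```python
import deepfat as df

phantom = df.generate_phantom(df.PhantomSpec(noise_sd=0.0), seed=1)
result = df.quantify_eat(phantom.ct, phantom.sac)
print(f"analytic EAT volume : {phantom.truth_eat_cm3:.3f} cm^3")
print(f"recovered EAT volume: {result.total_volume_cm3:.3f} cm^3")
print(f"mean fat attenuation: {result.mean_hu:.1f} HU")
```

prints

```
analytic EAT volume : 8.742 cm^3
recovered EAT volume: 8.742 cm^3
mean fat attenuation: -83.4 HU
```

At zero noise the phantom's compartment HU values guarantee voxel-exact
recovery, so the recovered volume equals the analytic truth, and the mean
fat attenuation lies inside the [−190, −30] HU fat window (pulled slightly
above the −100 HU tissue mean because the median filter mixes boundary
voxels with the warmer wall and blood).
The `examples/` directory holds one short script per capability: phantom
quantification, bisect sequencing, training the reference segmenter, and
agreement analytics.

A thin CLI wraps the same functions for shell use:

```bash
deepfat phantom --out scans --n 2 --seed 1
deepfat segment scans/phantom_000/series --extent 4,27 \
    --oracle-truth scans/phantom_000/sac_interior.nii.gz --out results
```

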