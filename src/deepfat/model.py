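"""Per-slice segmentation: the segmenter contract, the training procedure
(Adam, soft Dice loss, batch 20, max 30 epochs, lr 1e-3, early stop on a
1e-5 validation-Dice tolerance), and full-volume inference that reassembles
the bisected presentation order.

The production backbone in the original method is a large pretrained
semantic-segmentation network; here the backbone is a pluggable contract.
Two implementations ship: :class:`OracleSegmenter`, a test double that
returns ground truth, and :class:`TinyUNet`, a ~10k-parameter numpy
encoder-decoder with skip connections that trains on one CPU and serves as
the reference model for end-to-end experiments on phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from deepfat import _nn
from deepfat.augment import AugmentConfig, blur_duplicate, random_geometric
from deepfat.preprocess import (
    Slab,
    SlabPlan,
    WindowSpec,
    assemble_slab,
    bisect_plan,
    hu_window_to_8bit,
)
from deepfat.volume_io import CTVolume, HeartExtent, MaskVolume

__all__ = [
    "SliceSegmenter",
    "OracleSegmenter",
    "TinyUNet",
    "TrainingConfig",
    "TrainingLog",
    "soft_dice_loss",
    "train_segmenter",
    "segment_volume",
    "make_dataset",
]

F32 = np.float32


@runtime_checkable
class SliceSegmenter(Protocol):
    """Maps a 3-channel slab to a binary mask of its target slice."""

    def predict(self, slab: Slab) -> np.ndarray: ...


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol for the per-slice segmenter."""

    batch_size: int = 20
    max_epochs: int = 30
    initial_lr: float = 1e-3
    stop_tolerance: float = 1e-5  # on the change in validation Dice
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1 or self.stop_tolerance <= 0:
            raise ValueError("invalid training configuration")


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def soft_dice_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss 1 - (2 Σ p t + eps) / (Σ p + Σ t + eps) on one slice.

    Immune to foreground prevalence: an all-background slice predicted
    empty scores ~0 loss regardless of image size.
    """
    p = np.asarray(pred, dtype=F32)
    t = np.asarray(truth, dtype=F32)
    if p.shape != t.shape:
        raise ValueError("pred/truth shapes differ")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("pred must lie in [0, 1]")
    loss, _ = _nn.soft_dice_batch(p[None], t[None], eps=eps)
    return loss


class OracleSegmenter:
    """Test double returning the ground-truth mask for every target slice."""

    def __init__(self, truth: MaskVolume, extent: HeartExtent):
        self.truth = truth
        self.extent = extent

    def predict(self, slab: Slab) -> np.ndarray:
        return self.truth.voxels[self.extent.bottom + slab.target].copy()


class TinyUNet:
    """~10k-parameter encoder-decoder with skip connections, in numpy.

    Two 2x-downsampling levels (8/16/32 channels), nearest-neighbour
    upsampling with concatenated skips (8 and 4 decoder channels), a 1x1
    output head and a sigmoid.  Inputs are 3-channel 8-bit slabs scaled to
    [0, 1]; the binarization threshold for predictions is 0.5.
    """

    THRESHOLD = 0.5

    def __init__(self, seed: int = 0, channels=(8, 16, 32, 8, 4)):
        c1, c2, c3, d2, d1 = channels
        rng = np.random.default_rng(seed)

        def he(fan_in, fan_out):
            return (
                rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            ).astype(F32)

        self.channels = tuple(channels)
        # conv weights are stored as (9 * C_in, C_out) im2col matrices
        self.w1 = he(9 * 3, c1); self.b1 = np.zeros(c1, F32)
        self.w2 = he(9 * c1, c2); self.b2 = np.zeros(c2, F32)
        self.w3 = he(9 * c2, c3); self.b3 = np.zeros(c3, F32)
        self.w4 = he(9 * (c3 + c2), d2); self.b4 = np.zeros(d2, F32)
        self.w5 = he(9 * (d2 + c1), d1); self.b5 = np.zeros(d1, F32)
        self.w6 = he(d1, 1); self.b6 = np.zeros(1, F32)

    # -- parameter plumbing -------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3,
                self.w4, self.b4, self.w5, self.b5, self.w6, self.b6]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters))

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray, keep: bool = False):
        """x: (N, H, W, 3) float32 in [0, 1]; H, W divisible by 4."""
        cache = {}
        z1, cols1 = _nn.conv2d_forward(x, self.w1, self.b1)
        a1 = np.maximum(z1, 0.0)
        p1, m1 = _nn.maxpool2_forward(a1)
        z2, cols2 = _nn.conv2d_forward(p1, self.w2, self.b2)
        a2 = np.maximum(z2, 0.0)
        p2, m2 = _nn.maxpool2_forward(a2)
        z3, cols3 = _nn.conv2d_forward(p2, self.w3, self.b3)
        a3 = np.maximum(z3, 0.0)
        u2 = _nn.upsample2(a3)
        cat2 = np.concatenate([u2, a2], axis=3)
        z4, cols4 = _nn.conv2d_forward(cat2, self.w4, self.b4)
        a4 = np.maximum(z4, 0.0)
        u1 = _nn.upsample2(a4)
        cat1 = np.concatenate([u1, a1], axis=3)
        z5, cols5 = _nn.conv2d_forward(cat1, self.w5, self.b5)
        a5 = np.maximum(z5, 0.0)
        z6 = a5 @ self.w6 + self.b6
        prob = _nn.sigmoid(z6[..., 0])
        if keep:
            cache.update(
                x=x, z1=z1, a1=a1, m1=m1, p1=p1, z2=z2, a2=a2, m2=m2, p2=p2,
                z3=z3, a3=a3, cat2=cat2, z4=z4, a4=a4, cat1=cat1, z5=z5, a5=a5,
                cols1=cols1, cols2=cols2, cols3=cols3, cols4=cols4, cols5=cols5,
            )
        return prob, cache

    def _backward(self, dz6_2d: np.ndarray, cache) -> list[np.ndarray]:
        """Input is dL/dz6 (already through the sigmoid), shape (N, H, W)."""
        c = cache
        dz6 = dz6_2d[..., None]
        d1n = self.w6.shape[0]
        dw6 = c["a5"].reshape(-1, d1n).T @ dz6.reshape(-1, 1)
        db6 = np.array([dz6.sum()], dtype=F32)
        da5 = dz6 @ self.w6.T
        dz5 = da5 * (c["z5"] > 0)
        dw5, db5, dcat1 = _nn.conv2d_backward(dz5, c["cols5"], self.w5, c["cat1"].shape)
        d2c = self.w4.shape[1]  # decoder channels at the half-resolution level
        du1, da1_skip = dcat1[..., :d2c], dcat1[..., d2c:]
        da4 = _nn.upsample2_backward(du1)
        dz4 = da4 * (c["z4"] > 0)
        dw4, db4, dcat2 = _nn.conv2d_backward(dz4, c["cols4"], self.w4, c["cat2"].shape)
        c3n = self.w3.shape[1]
        du2, da2_skip = dcat2[..., :c3n], dcat2[..., c3n:]
        da3 = _nn.upsample2_backward(du2)
        dz3 = da3 * (c["z3"] > 0)
        dw3, db3, dp2 = _nn.conv2d_backward(dz3, c["cols3"], self.w3, c["p2"].shape)
        da2 = _nn.maxpool2_backward(dp2, c["m2"]) + da2_skip
        dz2 = da2 * (c["z2"] > 0)
        dw2, db2, dp1 = _nn.conv2d_backward(dz2, c["cols2"], self.w2, c["p1"].shape)
        da1 = _nn.maxpool2_backward(dp1, c["m1"]) + da1_skip
        dz1 = da1 * (c["z1"] > 0)
        dw1, db1, _ = _nn.conv2d_backward(
            dz1, c["cols1"], self.w1, c["x"].shape, need_dx=False
        )
        return [dw1, db1, dw2, db2, dw3, db3, dw4, db4, dw5, db5, dw6, db6]

    # -- public API ---------------------------------------------------------
    @staticmethod
    def _to_input(slabs: list[Slab]) -> np.ndarray:
        x = np.stack([s.channels for s in slabs]).astype(F32) / 255.0
        return np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # channels-last

    def predict_proba(self, slabs: list[Slab], chunk: int = 32) -> np.ndarray:
        """Foreground probabilities for a list of slabs, shape (N, H, W)."""
        x = self._to_input(slabs)
        out = np.empty(x.shape[:3], dtype=F32)
        for i in range(0, len(x), chunk):
            out[i : i + chunk], _ = self._forward(x[i : i + chunk])
        return out

    def predict(self, slab: Slab) -> np.ndarray:
        prob = self.predict_proba([slab])[0]
        return (prob >= self.THRESHOLD).astype(np.uint8)

    def train_step(self, slabs: list[Slab], masks: np.ndarray, opt: _nn.Adam) -> float:
        x = self._to_input(slabs)
        prob, cache = self._forward(x, keep=True)
        loss, dprob = _nn.soft_dice_batch(prob, masks.astype(F32))
        dz6 = dprob * prob * (1.0 - prob)  # through the sigmoid
        grads = self._backward(dz6, cache)
        opt.step(grads)
        return loss

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path, config: TrainingConfig | None = None) -> None:
        """Single-file weights (.npz) + JSON sidecar with run metadata."""
        path = Path(path)
        names = ["w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4", "w5", "b5",
                 "w6", "b6"]
        np.savez(path, channels=np.array(self.channels),
                 **{n: getattr(self, n) for n in names})
        sidecar = {"model": "TinyUNet", "channels": list(self.channels),
                   "n_parameters": self.n_parameters}
        if config is not None:
            sidecar["training"] = {
                "batch_size": config.batch_size,
                "max_epochs": config.max_epochs,
                "initial_lr": config.initial_lr,
                "stop_tolerance": config.stop_tolerance,
                "seed": config.seed,
            }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TinyUNet":
        data = np.load(str(path))
        model = cls(channels=tuple(int(c) for c in data["channels"]))
        for n in ["w1", "b1", "w2", "b2", "w3", "b3", "w4", "b4", "w5", "b5",
                  "w6", "b6"]:
            setattr(model, n, data[n].astype(F32))
        return model


def make_dataset(
    volumes: list[tuple[CTVolume, HeartExtent, MaskVolume]],
    window: WindowSpec = WindowSpec(),
    plan_fn=bisect_plan,
) -> list[tuple[Slab, np.ndarray]]:
    """Window each volume, apply the slab plan, pair slabs with truth slices.

    ``plan_fn`` is :func:`bisect_plan` by default; pass
    :func:`deepfat.preprocess.sequential_plan` for the no-bisect ablation.
    """
    out: list[tuple[Slab, np.ndarray]] = []
    for ct, extent, truth in volumes:
        v8 = hu_window_to_8bit(ct, window)[extent.bottom : extent.top + 1]
        for k, s in plan_fn(extent):
            slab = assemble_slab(v8, k, s)
            mask = truth.voxels[extent.bottom + k].copy()
            out.append((slab, mask))
    return out


def _mean_slice_dice(model: TinyUNet, val: list[tuple[Slab, np.ndarray]]) -> float:
    from deepfat.evaluate import dice  # local import avoids a cycle

    probs = model.predict_proba([s for s, _ in val])
    preds = probs >= model.THRESHOLD
    return float(np.mean([dice(p, m) for p, (_, m) in zip(preds, val)]))


def train_segmenter(
    model: TinyUNet,
    train: list[tuple[Slab, np.ndarray]],
    val: list[tuple[Slab, np.ndarray]],
    config: TrainingConfig = TrainingConfig(),
    augment: AugmentConfig | None = AugmentConfig(),
) -> tuple[TinyUNet, TrainingLog]:
    """Mini-batch Adam optimization of the soft Dice loss.

    Blur duplication is applied once up front; a fresh rotation/scale draw
    is applied to every training item each epoch.  Validation (mean slice
    Dice on unaugmented slabs) runs at the end of each epoch; training
    stops when its change falls below ``stop_tolerance`` or at
    ``max_epochs``.
    """
    if not train or not val:
        raise ValueError("train and val datasets must be non-empty")
    shapes = {s.shape for s, _ in train} | {s.shape for s, _ in val}
    if len(shapes) != 1:
        raise ValueError(f"all slabs must share one shape, got {shapes}")

    rng = np.random.default_rng(config.seed)
    if augment is not None:
        train = blur_duplicate(train, augment, rng)
    opt = _nn.Adam(model.parameters, lr=config.initial_lr)
    log = TrainingLog()

    for epoch in range(config.max_epochs):
        if augment is not None:
            epoch_items = [random_geometric(s, m, augment, rng) for s, m in train]
        else:
            epoch_items = train
        order = rng.permutation(len(epoch_items))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            slabs = [epoch_items[i][0] for i in idx]
            masks = np.stack([epoch_items[i][1] for i in idx])
            losses.append(model.train_step(slabs, masks, opt))
        log.train_loss.append(float(np.mean(losses)))
        log.val_dice.append(_mean_slice_dice(model, val))
        if (
            epoch > 0
            and abs(log.val_dice[-1] - log.val_dice[-2]) < config.stop_tolerance
        ):
            log.stop_reason = "tolerance"
            break
    else:
        log.stop_reason = "max_epochs"
    return model, log


def segment_volume(
    volume: CTVolume,
    extent: HeartExtent,
    model: SliceSegmenter,
    window: WindowSpec = WindowSpec(),
    plan_fn=bisect_plan,
) -> MaskVolume:
    """Predict the sac-interior mask for every heart slice of a volume.

    Pipeline: HU-attention-window -> slab plan -> per-slice prediction ->
    masks placed back at their anatomical indices.  Slices outside the
    extent are zero; each in-extent slice is predicted exactly once, so the
    output does not depend on the presentation order.
    """
    extent.validate_for(volume)
    v8 = hu_window_to_8bit(volume, window)[extent.bottom : extent.top + 1]
    out = np.zeros(volume.voxels.shape, dtype=np.uint8)
    for k, s in plan_fn(extent):
        pred = model.predict(assemble_slab(v8, k, s))
        if pred.shape != v8.shape[1:]:
            raise ValueError("segmenter output shape mismatch")
        out[extent.bottom + k] = (np.asarray(pred) > 0).astype(np.uint8)
    return MaskVolume(voxels=out, spacing=volume.spacing, label="sac-interior")
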