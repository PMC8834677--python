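"""Training and inference for the four-chamber segmentation U-Net.

The training recipe mirrors the study protocol: mini-batch SGD with a
momentum optimizer (batch size 10, learning rate 0.002, weight decay
0.0005, 100 epochs at full scale), data augmentation by random rotation in
+/-5 degrees and random vertical flip, per-pixel softmax cross-entropy, and
model selection by best validation mean foreground Dice.  Desk-scale
configurations (64x64 frames, depth 2, few epochs) use the same code path.
"""

from __future__ import annotations

import io as _stdio
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import CineSequence
from .metrics import dice
from .unet import SGDMomentum, UNet, clip_gradients, cross_entropy_with_grad, softmax


@dataclass
class UNetConfig:
    """Architecture and optimisation settings.

    Defaults follow the full-scale protocol; `depth`/`base_filters` are the
    canonical U-Net shrunk to a 128 grid.  ``in_size`` must be divisible by
    ``2**depth``.
    """

    in_size: int = 128
    n_classes: int = 5
    depth: int = 4
    base_filters: int = 32
    epochs: int = 100
    batch_size: int = 10
    learning_rate: float = 0.002
    momentum: float = 0.9
    weight_decay: float = 0.0005
    aug_rotation_deg: float = 5.0
    aug_flip_vertical: bool = True
    lr_schedule: str = "constant"  # "constant" | "warmcos"
    input_norm: str = "standard"  # per-frame standardization | "unit" ([0,1])
    coord_channels: bool = True  # append fixed (row, col) input channels
    grad_clip: float = 2.0  # global gradient-norm ceiling (0 disables)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_size % (2**self.depth) != 0:
            raise ValueError(
                f"in_size {self.in_size} must be divisible by 2^depth={2**self.depth}"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.lr_schedule not in ("constant", "warmcos"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


@dataclass
class TrainedModel:
    """A trained network plus its config and per-epoch training log."""

    config: UNetConfig
    model: UNet
    training_log: list[dict] = field(default_factory=list)

    @property
    def best_val_dsc(self) -> float:
        if not self.training_log:
            return float("nan")
        return max(e["val_dsc"] for e in self.training_log)


def augment(
    frame: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    rotation_deg: float = 5.0,
    flip_vertical: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Random rotation (bilinear frame / nearest mask) + vertical flip.

    The rotation angle is uniform in [-rotation_deg, +rotation_deg]; the
    flip is applied with probability 0.5, identically to frame and mask.
    Mask labels are never interpolated.
    """
    if frame.shape != mask.shape:
        raise ValueError(f"frame {frame.shape} and mask {mask.shape} differ")
    angle = float(rng.uniform(-rotation_deg, rotation_deg))
    do_flip = flip_vertical and bool(rng.random() < 0.5)
    if angle != 0.0:
        f = ndimage.rotate(frame.astype(np.float32), angle, reshape=False, order=1, mode="nearest")
        m = ndimage.rotate(mask, angle, reshape=False, order=0, mode="nearest")
    else:
        f, m = frame.astype(np.float32), mask.copy()
    if do_flip:
        f, m = f[::-1].copy(), m[::-1].copy()
    return f, m


def build_unet(config: UNetConfig) -> UNet:
    """Instantiate an untrained U-Net; identical weights for equal seeds."""
    return UNet(
        in_size=config.in_size,
        n_classes=config.n_classes,
        depth=config.depth,
        base_filters=config.base_filters,
        seed=config.seed,
        input_norm=config.input_norm,
        coord_channels=config.coord_channels,
    )


def _normalize(frames: np.ndarray, mode: str = "standard") -> np.ndarray:
    """8-bit frames to float32 NCHW with one channel.

    ``standard`` standardizes each frame to zero mean / unit variance
    (robust to window differences and the better-conditioned input for
    short training runs); ``unit`` simply maps to [0, 1].
    """
    x = np.asarray(frames, dtype=np.float32)
    if mode == "unit":
        x = x / 255.0
    else:
        mu = x.mean(axis=(-2, -1), keepdims=True)
        sd = x.std(axis=(-2, -1), keepdims=True)
        x = (x - mu) / np.maximum(sd, 1e-6)
    if x.ndim == 2:
        x = x[None]
    return x[:, None]


def mean_foreground_dsc(model: UNet, frames: np.ndarray, masks: np.ndarray, n_classes: int = 5) -> float:
    """Mean Dice over chamber classes and images of the argmax prediction."""
    pred = predict_labels(model, frames)
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # both-empty dice warnings
        for i in range(frames.shape[0]):
            for c in range(1, n_classes):
                scores.append(dice(masks[i] == c, pred[i] == c))
    return float(np.mean(scores))


def train(
    model: UNet | None,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: UNetConfig,
) -> TrainedModel:
    """Train with SGD+momentum; keep the best-validation-DSC weights.

    ``train_set``/``val_set`` are ``(frames, masks)`` with frames uint8
    ``(N, H, W)`` and masks int ``(N, H, W)``.  Deterministic given
    ``config.seed`` at a fixed thread count.
    """
    tr_frames, tr_masks = train_set
    if tr_frames.shape[0] == 0:
        raise ValueError("empty training set")
    if tr_frames.shape[1] != config.in_size:
        raise ValueError(
            f"training frames are {tr_frames.shape[1:]} but config.in_size={config.in_size}"
        )
    if model is None:
        model = build_unet(config)
    rng = np.random.default_rng(config.seed)
    opt = SGDMomentum(
        model, lr=config.learning_rate, momentum=config.momentum, weight_decay=config.weight_decay
    )
    n = tr_frames.shape[0]
    log: list[dict] = []
    best_dsc, best_weights = -np.inf, model.get_weights()

    steps_per_epoch = -(-n // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    warmup = max(1, total_steps // 10)
    step = 0

    def _lr_at(k: int) -> float:
        """Warmup-cosine: linear ramp over the first 10% of steps, then
        cosine decay to a tenth of the peak rate."""
        peak = config.learning_rate
        if config.lr_schedule == "constant":
            return peak
        if k < warmup:
            return peak * (k + 1) / warmup
        frac = (k - warmup) / max(total_steps - warmup, 1)
        return peak * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))

    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch_f = np.empty((len(idx), config.in_size, config.in_size), np.float32)
            batch_m = np.empty((len(idx), config.in_size, config.in_size), np.int64)
            for j, i in enumerate(idx):
                f, m = augment(
                    tr_frames[i],
                    tr_masks[i],
                    rng,
                    rotation_deg=config.aug_rotation_deg,
                    flip_vertical=config.aug_flip_vertical,
                )
                batch_f[j], batch_m[j] = f, m
            x = _normalize(batch_f, config.input_norm)
            logits = model.forward(x, train=True)
            loss, dlogits = cross_entropy_with_grad(logits, batch_m)
            model.backward(dlogits)
            if config.grad_clip > 0:
                clip_gradients(model, config.grad_clip)
            opt.lr = _lr_at(step)
            opt.step()
            step += 1
            epoch_loss += loss
            n_batches += 1
        val_dsc = mean_foreground_dsc(model, val_set[0], val_set[1], config.n_classes)
        log.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_dsc": val_dsc})
        if val_dsc > best_dsc:
            best_dsc = val_dsc
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    return TrainedModel(config=config, model=model, training_log=log)


def predict_probs(model: UNet, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Per-frame class probability stacks ``(N, n_classes, H, W)``."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1] != model.in_size or frames.shape[2] != model.in_size:
        raise ValueError(
            f"frames {frames.shape[1:]} do not match model in_size {model.in_size}"
        )
    out = []
    for start in range(0, frames.shape[0], batch_size):
        x = _normalize(frames[start : start + batch_size], model.input_norm)
        logits = model.forward(x, train=False)
        out.append(softmax(logits, axis=1))
    return np.concatenate(out, axis=0)


def predict_labels(model: UNet, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Argmax label maps ``(N, H, W)`` of :func:`predict_probs`."""
    return predict_probs(model, frames, batch_size).argmax(axis=1).astype(np.int64)


def predict_cine(trained: TrainedModel, cine: CineSequence) -> np.ndarray:
    """Probability stacks for every phase of a cine (no randomness)."""
    return predict_probs(trained.model, np.asarray(cine.frames))


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(trained: TrainedModel, path: Path | str) -> None:
    """Self-describing single-file checkpoint (config + weights + log)."""
    meta = {"config": asdict(trained.config), "training_log": trained.training_log}
    arrays = trained.model.get_weights()
    buf = _stdio.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: Path | str) -> TrainedModel:
    """Rebuild a :class:`TrainedModel`; predictions are bit-identical."""
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        weights = {k: data[k] for k in data.files if k != "meta"}
    config = UNetConfig(**meta["config"])
    model = build_unet(config)
    model.set_weights(weights)
    return TrainedModel(config=config, model=model, training_log=meta["training_log"])
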