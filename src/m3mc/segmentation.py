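"""2-D slice-wise multiclass segmentation networks (S-Net).

Four U-shaped families are provided — a plain U-Net, an attention U-Net
(additive attention gates on the skip connections), a densely connected
encoder U-Net, and a SegNet (pooling-index unpooling, no skip
concatenation). All share the same decoder contract: per level a 2×2
upsampling (or unpooling), an optional skip connection, and two
convolutional blocks of 3×3 convolution + batch norm + ReLU; a final 1×1
convolution and softmax yield per-pixel probabilities over the three
classes (background / M3 / MC).

The families are faithful to their topologies at configurable depth and
width rather than to the layer counts of the original publications, so they
train at desk scale on CPU. Training uses the soft Dice loss with Adam and
a reduce-on-plateau learning-rate schedule.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .volume_io import MultiClassMask, Volume3D, normalize_intensity

ARCHITECTURES = ("plain_unet", "attention_unet", "dense_unet", "segnet")

__all__ = [
    "SegModelConfig",
    "SegTrainSpec",
    "build_segmentation_model",
    "dice_loss",
    "train_segmentation",
    "predict_mask",
    "save_model",
    "load_model",
    "ARCHITECTURES",
]


@dataclass
class SegModelConfig:
    architecture: str = "plain_unet"
    depth: int = 3
    base_filters: int = 8
    classes: int = 3
    input_size: tuple[int, int] = (64, 64)
    pretrained_encoder: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.classes != 3:
            raise ValueError("the segmentation task has exactly 3 classes")
        h, w = self.input_size
        if h % (2**self.depth) or w % (2**self.depth):
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2^depth={2**self.depth}"
            )


@dataclass
class SegTrainSpec:
    """Training recipe; the clinical-scale defaults are learning rate
    2.5e-4 reduced on plateau by 0.5 with patience 25 over up to 300
    epochs, Dice loss, Adam, batch size 8."""

    learning_rate: float = 2.5e-4
    plateau_factor: float = 0.5
    plateau_patience: int = 25
    schedule: str = "plateau"  # or "step"
    max_epochs: int = 300
    batch_size: int = 8
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau factor must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, rng, ndim=2):
        super().__init__()
        self.conv1 = nn.Conv(cin, cout, 3, ndim=ndim, rng=rng)
        self.bn1 = nn.BatchNorm(cout)
        self.conv2 = nn.Conv(cout, cout, 3, ndim=ndim, rng=rng)
        self.bn2 = nn.BatchNorm(cout)

    def __call__(self, x):
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class _AttentionGate(nn.Module):
    """Additive attention on a skip connection: the gating signal from the
    coarser decoder path modulates the encoder features."""

    def __init__(self, gate_channels, skip_channels, rng):
        super().__init__()
        inter = max(skip_channels // 2, 1)
        self.wg = nn.Conv(gate_channels, inter, 1, ndim=2, rng=rng)
        self.wx = nn.Conv(skip_channels, inter, 1, ndim=2, rng=rng)
        self.psi = nn.Conv(inter, 1, 1, ndim=2, rng=rng)

    def __call__(self, gate, skip):
        a = (self.wg(gate) + self.wx(skip)).relu()
        return skip * self.psi(a).sigmoid()


class _DenseBlock(nn.Module):
    """Densely connected block: each layer sees the concatenation of all
    previous feature maps and contributes ``growth`` channels."""

    def __init__(self, cin, growth, n_layers, rng):
        super().__init__()
        self.convs = []
        self.bns = []
        channels = cin
        for _ in range(n_layers):
            self.convs.append(nn.Conv(channels, growth, 3, ndim=2, rng=rng))
            self.bns.append(nn.BatchNorm(growth))
            channels += growth
        self.out_channels = channels

    def __call__(self, x):
        feats = [x]
        for conv, bn in zip(self.convs, self.bns):
            h = nn.concat(feats, axis=1) if len(feats) > 1 else feats[0]
            feats.append(bn(conv(h)).relu())
        return nn.concat(feats, axis=1)


class SegModel(nn.Module):
    """U-shaped slice segmenter; family-specific wiring in forward()."""

    def __init__(self, config: SegModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, b = config.depth, config.base_filters
        arch = config.architecture
        enc_channels = [b * 2**i for i in range(d)]
        if config.pretrained_encoder:
            raise NotImplementedError(
                "pretrained encoder weights are not bundled; train from random init"
            )

        self.encoders = []
        cin = 1
        if arch == "dense_unet":
            self.transitions = []
            for c in enc_channels:
                block = _DenseBlock(cin, growth=max(c // 2, 4), n_layers=2, rng=rng)
                self.encoders.append(block)
                trans = nn.Conv(block.out_channels, c, 1, ndim=2, rng=rng)
                self.transitions.append(trans)
                cin = c
        else:
            for c in enc_channels:
                self.encoders.append(_ConvBlock(cin, c, rng))
                cin = c

        self.bottleneck = _ConvBlock(enc_channels[-1], enc_channels[-1] * 2, rng)

        self.decoders = []
        self.gates = []
        cin = enc_channels[-1] * 2
        for c in reversed(enc_channels):
            if arch == "segnet":
                # a 1x1 channel-match precedes index unpooling, so the
                # decoder block sees c channels, not cin
                self.decoders.append(_ConvBlock(c, c, rng))
            else:
                self.decoders.append(_ConvBlock(cin + c, c, rng))
            if arch == "attention_unet":
                self.gates.append(_AttentionGate(cin, c, rng))
            cin = c
        # SegNet upsamples through unpooling, which needs matching channel
        # counts between the pooled encoder map and the decoder input
        if arch == "segnet":
            self.channel_match = [
                nn.Conv(cin_c, c, 1, ndim=2, rng=rng)
                for cin_c, c in zip([enc_channels[-1] * 2] + list(reversed(enc_channels))[:-1],
                                    reversed(enc_channels))
            ]
        self.head = nn.Conv(enc_channels[0], config.classes, 1, ndim=2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> per-pixel class probabilities (N, classes, H, W)."""
        arch = self.config.architecture
        skips, pool_states = [], []
        for i, enc in enumerate(self.encoders):
            h = enc(x)
            if arch == "dense_unet":
                h = self.transitions[i](h).relu()
            skips.append(h)
            x, state = nn.max_pool(h, (2, 2))
            pool_states.append(state)
        x = self.bottleneck(x)
        for i, dec in enumerate(self.decoders):
            skip = skips[-(i + 1)]
            if arch == "segnet":
                x = self.channel_match[i](x)
                x = nn.max_unpool(x, pool_states[-(i + 1)])
            else:
                x = nn.upsample_nearest(x, (2, 2))
                if arch == "attention_unet":
                    skip = self.gates[i](x, skip)
                x = nn.concat([x, skip], axis=1)
            x = dec(x)
        return nn.softmax(self.head(x), axis=1)


def build_segmentation_model(cfg: SegModelConfig) -> SegModel:
    return SegModel(cfg)


def dice_loss(pred: Tensor, target, eps: float = 1e-6) -> Tensor:
    """1 − mean-over-classes soft Dice between predicted probabilities and
    one-hot targets, both shaped (N, C, H, W)."""
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=np.float64))
    if pred.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {t.shape}")
    axes = (0,) + tuple(range(2, pred.ndim))
    inter = (pred * t).sum(axis=axes)
    denom = pred.sum(axis=axes) + t.sum(axis=axes)
    dice_per_class = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - dice_per_class.mean()


def one_hot(labels: np.ndarray, classes: int = 3) -> np.ndarray:
    """(...,) int labels -> (classes, ...) one-hot float array."""
    out = np.zeros((classes,) + labels.shape, dtype=np.float64)
    for c in range(classes):
        out[c] = labels == c
    return out


def extract_slices(volume: Volume3D, mask: MultiClassMask | None = None):
    """Axial (z) slices of a min-max-normalized volume as (1, H, W) arrays,
    with matching label slices when a mask is given."""
    norm = normalize_intensity(volume, "minmax").data
    xs, ys = [], []
    for z in range(norm.shape[2]):
        xs.append(norm[:, :, z][None, :, :])
        if mask is not None:
            ys.append(mask.labels[:, :, z])
    return xs, ys


def train_segmentation(model: SegModel, dataset, spec: SegTrainSpec | None = None):
    """Train on a list of ``(Volume3D, MultiClassMask)`` pairs.

    Slices are extracted axially from every volume; a seeded fraction forms
    the validation split driving the plateau schedule. Returns
    ``(model, history)`` where history has one row per epoch with train and
    validation Dice loss and the learning rate.
    """
    spec = spec or SegTrainSpec()
    pairs = list(dataset)
    if not pairs:
        raise ValueError("empty training dataset")
    xs, ys = [], []
    for volume, mask in pairs:
        sx, sy = extract_slices(volume, mask)
        xs.extend(sx)
        ys.extend(sy)
    x_all = np.stack(xs)  # (S, 1, H, W)
    y_all = np.stack([one_hot(y, model.config.classes) for y in ys])  # (S, C, H, W)

    rng = np.random.default_rng(spec.seed)
    n = len(x_all)
    perm = rng.permutation(n)
    n_val = max(1, int(round(spec.val_fraction * n))) if n > 1 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = perm, perm

    opt = nn.Adam(model.parameters(), lr=spec.learning_rate)
    if spec.schedule == "plateau":
        sched = nn.ReduceLROnPlateau(opt, spec.plateau_factor, spec.plateau_patience)
    else:
        sched = nn.StepDecay(opt, spec.plateau_factor, spec.plateau_patience)

    history = []
    for epoch in range(spec.max_epochs):
        model.set_training(True)
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            pred = model(Tensor(x_all[idx]))
            loss = dice_loss(pred, y_all[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.set_training(False)
        val_losses = []
        for start in range(0, len(val_idx), spec.batch_size):
            idx = val_idx[start : start + spec.batch_size]
            val_losses.append(float(dice_loss(model(Tensor(x_all[idx])), y_all[idx]).data))
        val_loss = float(np.mean(val_losses)) if val_losses else float(np.mean(losses))
        sched.step(val_loss)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
    return model, pd.DataFrame(history)


def predict_mask(model: SegModel, volume: Volume3D, batch_size: int = 8) -> MultiClassMask:
    """Slice-wise argmax prediction restacked to the source grid."""
    h, w = model.config.input_size
    if volume.shape[0] != h or volume.shape[1] != w:
        raise ValueError(
            f"volume in-plane extent {volume.shape[:2]} does not match model input {(h, w)}"
        )
    model.set_training(False)
    xs, _ = extract_slices(volume)
    x_all = np.stack(xs)
    out = np.zeros(volume.shape, dtype=np.uint8)
    for start in range(0, len(x_all), batch_size):
        probs = model(Tensor(x_all[start : start + batch_size])).data
        out[:, :, start : start + probs.shape[0]] = np.argmax(probs, axis=1).transpose(1, 2, 0)
    return MultiClassMask(out, volume.spacing)


def save_model(model: SegModel, path) -> None:
    """Checkpoint: npz of arrays + JSON sidecar with the config."""
    path = Path(path)
    np.savez(path, **model.state_arrays())
    sidecar = path.with_suffix(".json")
    cfg = asdict(model.config)
    cfg["input_size"] = list(cfg["input_size"])
    sidecar.write_text(json.dumps({"kind": "segmentation", "config": cfg}, indent=2))


def load_model(path) -> SegModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    cfg["input_size"] = tuple(cfg["input_size"])
    model = SegModel(SegModelConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as arrays:
        model.load_state_arrays(dict(arrays))
    return model
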