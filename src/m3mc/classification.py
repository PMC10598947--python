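"""3-D distance-aware relationship classifier (C-Net).

A stack of levels, each 3×3×3 convolution → batch norm → ReLU → 2×2×2
max-pooling, followed by global average pooling, a dense layer, and a
softmax over the two classes (buccal / lingual). Input is the multichannel
crop centered at the closest M3–MC approach: any subset of {image, mask,
sdm} channels.

The default configuration is the desk-scale preset (32×32×16 crops, three
levels); :meth:`ClsModelConfig.clinical_scale` restores the clinical-scale
five-level network on 256×256×32 crops. When an axis reaches extent 1
before the last level, pooling is clamped to 1 on that axis and a debug
message is logged (relevant at clinical scale, where the depth axis hits 1
after five halvings).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .localization import MultichannelInput
from .nn import Tensor
from .phantom import RelationLabel

logger = logging.getLogger(__name__)

CLASSES = ("buccal", "lingual")

__all__ = [
    "ClsModelConfig",
    "ClsTrainSpec",
    "CNet",
    "build_cnet",
    "bce_loss",
    "train_cnet",
    "predict_relation",
    "save_model",
    "load_model",
    "CLASSES",
]


@dataclass
class ClsModelConfig:
    levels: int = 3
    base_filters: int = 8
    input_channels: int = 2
    input_size: tuple[int, int, int] = (32, 32, 16)
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not 1 <= self.input_channels <= 3:
            raise ValueError("input_channels must be 1..3")
        # each axis must survive `levels` rounds of halving-or-clamping:
        # divisible by 2 until it reaches 1
        for extent in self.input_size:
            e = extent
            for _ in range(self.levels):
                if e == 1:
                    continue
                if e % 2:
                    raise ValueError(
                        f"extent {extent} not divisible by 2 through {self.levels} levels"
                    )
                e //= 2

    @classmethod
    def clinical_scale(cls, input_channels: int = 2, base_filters: int = 8, seed: int = 0):
        """The clinical-scale preset: five levels on 256×256×32 crops."""
        return cls(
            levels=5,
            base_filters=base_filters,
            input_channels=input_channels,
            input_size=(256, 256, 32),
            seed=seed,
        )


@dataclass
class ClsTrainSpec:
    """Binary cross-entropy + Adam, learning rate 1e-3 reduced on plateau
    by 0.5, up to 100 epochs, batch size 1 (all as in the clinical recipe;
    batched training is allowed)."""

    learning_rate: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 25
    schedule: str = "plateau"
    max_epochs: int = 100
    batch_size: int = 1
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


class CNet(nn.Module):
    def __init__(self, config: ClsModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs, self.bns = [], []
        cin = config.input_channels
        for i in range(config.levels):
            cout = config.base_filters * 2**i
            self.convs.append(nn.Conv(cin, cout, 3, ndim=3, rng=rng))
            self.bns.append(nn.BatchNorm(cout))
            cin = cout
        self.dense = nn.Dense(cin, 2, rng=rng)
        self.record_activations = False
        self.level_activations: list[Tensor] = []

    def forward_logits(self, x: Tensor) -> Tensor:
        self.level_activations = []
        for conv, bn in zip(self.convs, self.bns):
            x = bn(conv(x)).relu()
            if self.record_activations:
                self.level_activations.append(x)
            factors = tuple(2 if s > 1 else 1 for s in x.shape[2:])
            if any(f == 1 for f in factors):
                logger.debug("pooling clamped to 1 on axes of extent 1: %s", x.shape[2:])
            x, _ = nn.max_pool(x, factors)
        return self.dense(nn.global_avg_pool(x))

    def __call__(self, x: Tensor) -> Tensor:
        """(N, C, X, Y, Z) -> class probabilities (N, 2), order (buccal, lingual)."""
        return nn.softmax(self.forward_logits(x), axis=1)


def build_cnet(cfg: ClsModelConfig) -> CNet:
    return CNet(cfg)


def bce_loss(pred: Tensor, target_onehot, eps: float = 1e-12) -> Tensor:
    """Cross-entropy of a two-class softmax (the binary cross-entropy of
    the positive-class probability)."""
    t = target_onehot if isinstance(target_onehot, Tensor) else Tensor(np.asarray(target_onehot))
    if pred.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {t.shape}")
    n = pred.shape[0]
    return -((pred + eps).log() * t).sum() * (1.0 / n)


def _label_index(label) -> int:
    value = label.value if isinstance(label, RelationLabel) else str(label)
    return CLASSES.index(value)


def _stack_inputs(inputs, config: ClsModelConfig):
    xs, ys = [], []
    for item in inputs:
        x, label = item
        if isinstance(x, MultichannelInput):
            if x.channels.shape[0] != config.input_channels:
                raise ValueError(
                    f"input has {x.channels.shape[0]} channels, model expects "
                    f"{config.input_channels}"
                )
            xs.append(x.channels)
        else:
            xs.append(np.asarray(x, dtype=np.float64))
        ys.append(_label_index(label))
    return np.stack(xs), np.asarray(ys)


def train_cnet(model: CNet, inputs, spec: ClsTrainSpec | None = None):
    """Train on ``(MultichannelInput, RelationLabel)`` pairs.

    Requires at least two examples with both classes present. A seeded
    validation split drives the plateau schedule. Returns
    ``(model, history)``.
    """
    spec = spec or ClsTrainSpec()
    inputs = list(inputs)
    if len(inputs) < 2:
        raise ValueError("need at least two training examples")
    x_all, y_idx = _stack_inputs(inputs, model.config)
    if len(set(y_idx.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    y_all = np.zeros((len(y_idx), 2))
    y_all[np.arange(len(y_idx)), y_idx] = 1.0

    rng = np.random.default_rng(spec.seed)
    n = len(x_all)
    perm = rng.permutation(n)
    n_val = int(round(spec.val_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0 or len(set(y_idx[train_idx].tolist())) < 2:
        train_idx, val_idx = perm, perm[:0]

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
            loss = bce_loss(pred, y_all[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.set_training(False)
        if len(val_idx):
            val_pred = model(Tensor(x_all[val_idx])).data
            val_loss = float(
                -np.mean(np.log(val_pred[np.arange(len(val_idx)), y_idx[val_idx]] + 1e-12))
            )
        else:
            val_loss = float(np.mean(losses))
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


def predict_relation(model: CNet, x: MultichannelInput) -> RelationLabel:
    """Argmax class with its probability for one multichannel crop."""
    if x.channels.shape[0] != model.config.input_channels:
        raise ValueError(
            f"input has {x.channels.shape[0]} channels, model expects "
            f"{model.config.input_channels}"
        )
    model.set_training(False)
    probs = model(Tensor(x.channels[None])).data[0]
    k = int(np.argmax(probs))
    return RelationLabel(CLASSES[k], float(probs[k]))


def predict_proba(model: CNet, inputs) -> np.ndarray:
    """(N, 2) class probabilities for a list of MultichannelInput."""
    model.set_training(False)
    x = np.stack([i.channels for i in inputs])
    return model(Tensor(x)).data


def save_model(model: CNet, path) -> None:
    path = Path(path)
    np.savez(path, **model.state_arrays())
    cfg = asdict(model.config)
    cfg["input_size"] = list(cfg["input_size"])
    path.with_suffix(".json").write_text(
        json.dumps({"kind": "classification", "config": cfg}, indent=2)
    )


def load_model(path) -> CNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    cfg["input_size"] = tuple(cfg["input_size"])
    model = CNet(ClsModelConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as arrays:
        model.load_state_arrays(dict(arrays))
    return model
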