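"""Grad-CAM explanations of the 3-D relationship classifier.

Gradient-weighted class activation mapping: the gradient of the target
class logit with respect to a convolutional level's activations is globally
average-pooled into per-channel weights, the weighted activation sum is
rectified, trilinearly upsampled to the input extent, and max-normalized to
[0, 1]. Well-trained distance-aware models concentrate the map around the
molar root and the canal periphery near the closest approach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy import ndimage

from .classification import CLASSES, CNet
from .localization import MultichannelInput
from .nn import Tensor
from .volume_io import Volume3D

__all__ = ["AttentionMap", "gradcam_3d", "overlay_heatmap"]


@dataclass
class AttentionMap:
    values: np.ndarray  # in [0, 1], co-registered with the classifier crop
    target_class: str
    layer: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("attention map values must lie in [0, 1]")


def gradcam_3d(model: CNet, x: MultichannelInput, target, layer: int = -1) -> AttentionMap:
    """Grad-CAM heatmap for ``target`` class at convolutional ``layer``.

    ``layer`` indexes the model's levels (negative from the end; default is
    the last level before the pooling head). All-zero rectified maps are
    returned as zeros, not errors.
    """
    if isinstance(target, str):
        class_idx = CLASSES.index(target)
        class_name = target
    else:
        class_idx = int(target)
        class_name = CLASSES[class_idx]
    n_levels = len(model.convs)
    if not -n_levels <= layer < n_levels:
        raise ValueError(f"layer index {layer} out of range for {n_levels} levels")

    model.set_training(False)
    model.record_activations = True
    try:
        logits = model.forward_logits(Tensor(x.channels[None]))
        activation = model.level_activations[layer]
        score = logits[0, class_idx]
        score.backward()
    finally:
        model.record_activations = False
    grads = activation.grad[0]  # (C, x, y, z)
    acts = activation.data[0]
    weights = grads.mean(axis=(1, 2, 3))
    cam = np.maximum((weights[:, None, None, None] * acts).sum(axis=0), 0.0)
    zoom = [t / s for t, s in zip(x.crop_shape, cam.shape)]
    cam = ndimage.zoom(cam, zoom, order=1)
    # guard against interpolation overshoot at the crop border
    cam = np.clip(cam, 0.0, None)[: x.crop_shape[0], : x.crop_shape[1], : x.crop_shape[2]]
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return AttentionMap(cam, class_name, layer % n_levels)


def overlay_heatmap(
    attention: AttentionMap,
    v: Volume3D,
    z: int,
    path=None,
    cmap: str = "jet",
    alpha: float = 0.6,
) -> np.ndarray:
    """Render one axial slice as grayscale with the heatmap alpha-blended on
    top. Returns the RGB uint8 image; writes a PNG when ``path`` is given.
    """
    if attention.values.shape != v.shape:
        raise ValueError("attention map and volume are not co-registered")
    if not 0 <= z < v.shape[2]:
        raise ValueError(f"slice {z} out of range for depth {v.shape[2]}")
    gray = np.asarray(v.data[:, :, z], dtype=np.float64)
    lo, hi = gray.min(), gray.max()
    gray = (gray - lo) / (hi - lo) if hi > lo else np.zeros_like(gray)
    heat = attention.values[:, :, z]
    color = colormaps[cmap](heat)[:, :, :3]
    a = (alpha * heat)[:, :, None]
    rgb = (1 - a) * gray[:, :, None] + a * color
    img = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    if path is not None:
        Image.fromarray(img.transpose(1, 0, 2)).save(str(path))
    return img
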