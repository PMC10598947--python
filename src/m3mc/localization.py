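"""Locate the M3–MC closest approach and assemble classifier inputs.

The classification stage does not see whole volumes: a fixed-size crop is
taken around the point where the third molar and the canal come closest,
and the requested channels (image, union mask, signed distance map) are
stacked in a canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .sdm import SignedDistanceMap
from .volume_io import LABEL_M3, LABEL_MC, MultiClassMask, Volume3D, normalize_intensity

CHANNEL_ORDER = ("image", "mask", "sdm")

__all__ = [
    "MultichannelInput",
    "closest_pair",
    "crop_classification_volume",
    "assemble_channels",
    "save_multichannel",
    "load_multichannel",
]


@dataclass
class MultichannelInput:
    """Co-registered cropped channel stack for the relationship classifier."""

    channels: np.ndarray  # (C, *crop_shape)
    channel_names: tuple[str, ...]
    center: tuple[int, int, int]
    crop_shape: tuple[int, int, int]

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 4:
            raise ValueError("channels must be a (C, X, Y, Z) stack")
        if self.channels.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel names")
        if tuple(self.channels.shape[1:]) != tuple(self.crop_shape):
            raise ValueError("channel grids do not match the declared crop shape")
        order = [CHANNEL_ORDER.index(c) for c in self.channel_names]
        if order != sorted(order):
            raise ValueError(f"channels must follow canonical order {CHANNEL_ORDER}")


def closest_pair(m: MultiClassMask):
    """Closest voxel pair between the M3 (label 1) and MC (label 2).

    Returns ``(point_m3, point_mc, distance_mm)``. Distances are Euclidean
    between voxel centers in mm; among all minimizing pairs the one with
    lexicographically smallest ``(z, y, x)`` M3 point, then MC point, is
    returned, so the result is deterministic. Contact (distance 0 between
    distinct labels) cannot occur on a single-label-per-voxel mask, but
    face-adjacent voxels return the spacing along that axis.
    """
    pts1 = np.argwhere(m.labels == LABEL_M3)
    pts2 = np.argwhere(m.labels == LABEL_MC)
    if len(pts1) == 0 or len(pts2) == 0:
        raise ValueError("closest_pair requires both labels 1 (M3) and 2 (MC) present")
    scale = np.asarray(m.spacing, dtype=np.float64)
    tree = cKDTree(pts2 * scale)
    dists, _ = tree.query(pts1 * scale)
    dmin = dists.min()
    # collect all minimizing pairs (ties within float reproduction of dmin)
    cand = np.flatnonzero(dists <= dmin + 1e-12)

    def zyx(p):
        return (int(p[2]), int(p[1]), int(p[0]))

    best = None
    for i in cand:
        a = pts1[i]
        # all label-2 voxels at the minimal distance from a
        neighbors = tree.query_ball_point(a * scale, dmin + 1e-12)
        for j in neighbors:
            b = pts2[j]
            key = (zyx(a), zyx(b))
            if best is None or key < best[0]:
                best = (key, tuple(int(c) for c in a), tuple(int(c) for c in b))
    return best[1], best[2], float(dmin)


def crop_classification_volume(fields, center, shape, pad_values=None):
    """Crop one or more co-registered grids to ``shape`` centered at ``center``.

    ``fields`` is a sequence of 3-D arrays; ``pad_values`` an optional
    per-field list of constants used outside the source grid (default 0).
    The crop window starts at ``center - shape//2`` on each axis, so the
    center voxel is always inside the crop.
    """
    center = tuple(int(c) for c in center)
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError("crop shape components must be >= 1")
    fields = [np.asarray(f) for f in fields]
    src_shape = fields[0].shape
    for f in fields:
        if f.shape != src_shape:
            raise ValueError("all fields must be co-registered (same shape)")
    if pad_values is None:
        pad_values = [0.0] * len(fields)
    starts = [c - s // 2 for c, s in zip(center, shape)]
    out = []
    for f, pv in zip(fields, pad_values):
        dst = np.full(shape, pv, dtype=np.float64)
        src_slices, dst_slices = [], []
        for ax in range(3):
            s0 = max(0, starts[ax])
            s1 = min(src_shape[ax], starts[ax] + shape[ax])
            if s0 >= s1:
                break
            src_slices.append(slice(s0, s1))
            dst_slices.append(slice(s0 - starts[ax], s1 - starts[ax]))
        else:
            dst[tuple(dst_slices)] = f[tuple(src_slices)]
        out.append(dst)
    return out


def assemble_channels(
    v: Volume3D,
    m: MultiClassMask,
    s: SignedDistanceMap | None,
    config,
    center=None,
    crop_shape=(256, 256, 32),
) -> MultichannelInput:
    """Build the classifier input: requested channels, canonically ordered,
    cropped around the closest M3–MC approach.

    * ``image`` — min-max normalized intensities, zero-padded;
    * ``mask`` — union (M3 ∪ MC) binary mask, zero-padded;
    * ``sdm`` — signed distance map passed through unscaled, padded with the
      maximum in-crop value (far-from-structure semantics; 0 would wrongly
      mean "on the boundary").

    ``center`` defaults to the floor midpoint of :func:`closest_pair`.
    """
    config = list(config)
    if not config:
        raise ValueError("at least one channel must be requested")
    unknown = set(config) - set(CHANNEL_ORDER)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    names = tuple(c for c in CHANNEL_ORDER if c in config)
    if "sdm" in names and s is None:
        raise ValueError("sdm channel requested but no SignedDistanceMap given")

    if center is None:
        a, b, _ = closest_pair(m)
        center = tuple((ai + bi) // 2 for ai, bi in zip(a, b))

    channels = []
    for name in names:
        if name == "image":
            grid = normalize_intensity(v, "minmax").data
            (crop,) = crop_classification_volume([grid], center, crop_shape, [0.0])
        elif name == "mask":
            (crop,) = crop_classification_volume([m.binary()], center, crop_shape, [0.0])
        else:  # sdm
            (raw,) = crop_classification_volume([s.values], center, crop_shape, [np.nan])
            inside = raw[np.isfinite(raw)]
            fill = inside.max() if inside.size else 0.0
            crop = np.where(np.isfinite(raw), raw, fill)
        channels.append(crop)
    return MultichannelInput(
        channels=np.stack(channels, axis=0),
        channel_names=names,
        center=tuple(int(c) for c in center),
        crop_shape=tuple(int(c) for c in crop_shape),
    )


def save_multichannel(x: MultichannelInput, path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Persist a crop as 4-D NIfTI (channels last) with a JSON sidecar
    recording the center and channel configuration."""
    import json

    import nibabel as nib

    path = Path(path)
    stack = np.moveaxis(x.channels, 0, -1).astype(np.float32)
    aff = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(stack, aff), str(path))
    sidecar = {
        "channels": list(x.channel_names),
        "center": list(x.center),
        "crop_shape": list(x.crop_shape),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_multichannel(path) -> MultichannelInput:
    import json

    import nibabel as nib

    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path!s}: expected a 4-D multichannel stack")
    return MultichannelInput(
        np.moveaxis(np.asarray(data, dtype=np.float64), -1, 0),
        tuple(meta["channels"]),
        tuple(meta["center"]),
        tuple(meta["crop_shape"]),
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")
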