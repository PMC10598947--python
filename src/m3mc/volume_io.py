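"""Volumes, masks, NIfTI I/O, and dataset-preparation transforms.

Conventions (fixed across the package):

* axis order ``(x, y, z)`` — ``x`` is the in-plane left–right (buccolingual
  after side normalization) axis, ``y`` the second in-plane
  (mesiodistal) axis, and ``z`` the axial slice index increasing
  inferior → superior;
* 0-based voxel indices;
* mask labels: 0 = background, 1 = mandibular third molar (M3),
  2 = mandibular canal (MC).

Volumes from the right side of the mandible are mirrored along ``x`` onto
the left-side convention before any downstream analysis, so "buccal" maps
to a consistent grid direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

LABEL_BACKGROUND, LABEL_M3, LABEL_MC = 0, 1, 2
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_M3, LABEL_MC})

__all__ = [
    "Volume3D",
    "MultiClassMask",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "flip_right_to_left",
    "crop_axial_roi",
    "normalize_intensity",
    "LABEL_BACKGROUND",
    "LABEL_M3",
    "LABEL_MC",
]


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as a 3-D volume/mask."""


@dataclass
class Volume3D:
    """A 3-D intensity grid with voxel spacing and a side tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    side: str = "unspecified"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.side not in {"left", "right", "unspecified"}:
            raise ValueError(f"side must be left/right/unspecified, got {self.side!r}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class MultiClassMask:
    """Integer label grid on the same lattice as its volume."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3-D label grid, got ndim={self.labels.ndim}")
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(f"labels must be within {sorted(VALID_LABELS)}, found {sorted(present)}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self):
        return self.labels.shape

    def binary(self, label: int | None = None) -> np.ndarray:
        """Binarize: union of M3 and MC by default, or a single label."""
        if label is None:
            return (self.labels > 0).astype(np.uint8)
        return (self.labels == label).astype(np.uint8)


# ---------------------------------------------------------------------------
# NIfTI round-trip


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_volume(v: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), _affine(v.spacing))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_volume(path, side: str = "unspecified") -> Volume3D:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises various header errors
        raise FormatError(f"cannot read {path!s} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path!s}: expected a 3-D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) != 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path!s}: header does not define positive voxel spacing")
    return Volume3D(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), side=side)


def write_mask(m: MultiClassMask, path) -> None:
    img = nib.Nifti1Image(m.labels.astype(np.uint8), _affine(m.spacing))
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


def read_mask(path) -> MultiClassMask:
    v = read_volume(path)
    labels = np.asarray(v.data)
    if not np.allclose(labels, np.round(labels)):
        raise FormatError(f"{path!s}: mask voxels are not integers")
    labels = np.round(labels).astype(np.int64)
    if labels.min() < 0 or labels.max() > 2:
        raise ValueError(f"{path!s}: mask labels outside {{0,1,2}}")
    return MultiClassMask(labels, v.spacing)


# ---------------------------------------------------------------------------
# Dataset-preparation transforms


def flip_right_to_left(v: Volume3D, m: MultiClassMask | None = None):
    """Mirror a right-side volume (and its mask) along the left–right axis.

    Applying it to an already-left volume logs a warning and returns the
    inputs unchanged. Flipping twice restores the data grid (involution);
    only the side tag records the normalization.
    """
    if v.side == "left":
        logger.warning("flip_right_to_left called on a left-side volume; no-op")
        return (v, m) if m is not None else (v, None)
    flipped_v = Volume3D(v.data[::-1, :, :].copy(), v.spacing, side="left")
    flipped_m = None
    if m is not None:
        flipped_m = MultiClassMask(m.labels[::-1, :, :].copy(), m.spacing)
    return flipped_v, flipped_m


def crop_axial_roi(v: Volume3D, center_xy, size) -> Volume3D:
    """Crop every axial slice to an in-plane window centered at ``center_xy``.

    Regions outside the grid are zero-padded so the output always has
    exactly the requested in-plane extent; the z extent is unchanged.
    """
    cx, cy = int(center_xy[0]), int(center_xy[1])
    sx, sy = int(size[0]), int(size[1])
    if sx < 1 or sy < 1:
        raise ValueError("crop size components must be >= 1")
    nx, ny, nz = v.shape
    out = np.zeros((sx, sy, nz), dtype=v.data.dtype)
    x0, y0 = cx - sx // 2, cy - sy // 2
    # overlap between [x0, x0+sx) and [0, nx)
    sx0, sx1 = max(0, x0), min(nx, x0 + sx)
    sy0, sy1 = max(0, y0), min(ny, y0 + sy)
    if sx0 < sx1 and sy0 < sy1:
        out[sx0 - x0 : sx1 - x0, sy0 - y0 : sy1 - y0, :] = v.data[sx0:sx1, sy0:sy1, :]
    return Volume3D(out, v.spacing, side=v.side)


def normalize_intensity(v: Volume3D, method: str = "minmax") -> Volume3D:
    """Per-volume intensity normalization (``minmax`` to [0,1] or ``zscore``)."""
    data = np.asarray(v.data, dtype=np.float64)
    if method == "minmax":
        lo, hi = data.min(), data.max()
        if hi <= lo:
            raise ValueError("constant volume: min-max normalization undefined")
        out = (data - lo) / (hi - lo)
    elif method == "zscore":
        sd = data.std()
        if sd == 0:
            raise ValueError("constant volume: z-score normalization undefined")
        out = (data - data.mean()) / sd
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return Volume3D(out, v.spacing, side=v.side)
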