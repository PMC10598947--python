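"""Synthetic CBCT-like phantoms of a third molar and mandibular canal.

Each phantom is a small axial volume (default 64×64×32 voxels at 0.2 mm
isotropic spacing, a desk-scale stand-in for clinical CBCT crops) holding:

* a multi-rooted tooth — an ellipsoidal crown with tapered roots descending
  toward the canal level (mask label 1);
* a cortical-rimmed tubular canal running mesiodistally (along ``y``) whose
  centerline passes either buccal (+x) or lingual (−x) to the tooth roots
  at the closest approach, curving away from the tooth elsewhere (the canal
  lumen is label 2; the bright cortical rim is intensity only);
* piecewise-constant tissue intensities on a 16-bit-like scale with
  additive Gaussian noise.

Volumes follow the left-side convention of :mod:`m3mc.volume_io`, so
"buccal" is the +x grid direction relative to the tooth axis. The mask
geometry is a deterministic function of the geometric parameters; the seed
only drives intensity noise (and, in :func:`generate_dataset`, the per-case
geometric jitter). Beam hardening, streaks, and other CBCT texture are
deliberately not modelled — the relationship classifier consumes geometry
more than texture.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .localization import closest_pair
from .volume_io import LABEL_M3, LABEL_MC, MultiClassMask, Volume3D, write_mask, write_volume

__all__ = ["PhantomSpec", "RelationLabel", "generate_phantom", "relation_oracle", "generate_dataset"]

BUCCAL, LINGUAL = "buccal", "lingual"


@dataclass
class RelationLabel:
    """Binary buccal/lingual relationship with a class probability."""

    value: str
    probability: float = 1.0

    def __post_init__(self):
        if self.value not in {BUCCAL, LINGUAL}:
            raise ValueError(f"relation must be '{BUCCAL}' or '{LINGUAL}', got {self.value!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


@dataclass
class PhantomSpec:
    """Geometry, intensity, and noise parameters of one phantom.

    Lengths are in voxels unless noted. ``clearance`` is the lateral gap
    between the root surface and the canal surface at closest approach;
    zero or negative values produce contact.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    relation: str = BUCCAL
    # canal
    canal_radius: float = 2.5
    canal_z: float = 9.0
    canal_curve_amp: float = 4.0
    rim_thickness: float = 1.5
    # tooth
    crown_semiaxes: tuple[float, float, float] = (7.0, 8.0, 6.0)
    crown_z: float = 22.0
    root_count: int = 2
    root_length: float = 10.0
    root_radius: float = 2.5
    # relationship
    clearance: float = 1.5
    # intensities (arbitrary 16-bit-like units)
    intensity_bone: float = 700.0
    intensity_tooth: float = 1600.0
    intensity_canal: float = 150.0
    intensity_rim: float = 1100.0
    noise_sd: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.shape):
            raise ValueError("grid shape components must be >= 16")
        if self.canal_radius < 1 or self.root_radius < 1 or min(self.crown_semiaxes) < 1:
            raise ValueError("radii and semi-axes must be >= 1 voxel")
        if self.relation not in {BUCCAL, LINGUAL}:
            raise ValueError(f"relation must be '{BUCCAL}' or '{LINGUAL}'")

    @property
    def lateral_offset(self) -> float:
        """Signed x-offset of the canal centerline from the tooth axis at
        closest approach (+ = buccal)."""
        magnitude = self.root_radius + self.canal_radius + self.clearance
        return magnitude if self.relation == BUCCAL else -magnitude


def _tooth_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    cx, cy = float(nx // 2), float(ny // 2)
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ax_, ay, az = spec.crown_semiaxes
    crown = ((x - cx) / ax_) ** 2 + ((y - cy) / ay) ** 2 + ((z - spec.crown_z) / az) ** 2 <= 1.0
    tooth = crown
    root_top = spec.crown_z - spec.crown_semiaxes[2] / 2.0
    root_tip = root_top - spec.root_length
    sep = max(2.0, spec.crown_semiaxes[1] / 2.0)
    if spec.root_count == 1:
        root_ys = [cy]
    else:
        root_ys = [float(round(v)) for v in np.linspace(cy - sep, cy + sep, spec.root_count)]
    for ry in root_ys:
        # constant-radius root cylinders keep `clearance` geometrically
        # exact at the closest approach to the canal
        in_z = (z >= root_tip) & (z <= root_top)
        root = in_z & (((x - cx) ** 2 + (y - ry) ** 2) <= spec.root_radius**2)
        tooth = tooth | root
    return tooth


def _canal_geometry(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    cx, cy = float(nx // 2), float(ny // 2)
    sign = 1.0 if spec.relation == BUCCAL else -1.0
    yy = np.arange(ny)
    t = (yy - cy) / (ny / 2.0)
    centerline_x = cx + spec.lateral_offset + sign * spec.canal_curve_amp * t**2
    centerline_z = np.full(ny, spec.canal_z)
    return centerline_x, centerline_z


def _radial2(spec: PhantomSpec) -> np.ndarray:
    """Squared in-plane (x, z) distance of every voxel to the canal
    centerline, per mesiodistal position y."""
    nx, ny, nz = spec.shape
    cl_x, cl_z = _canal_geometry(spec)
    x = np.arange(nx)[:, None, None]
    z = np.arange(nz)[None, None, :]
    return (x - cl_x[None, :, None]) ** 2 + (z - cl_z[None, :, None]) ** 2


def generate_phantom(spec: PhantomSpec):
    """Render one phantom. Returns ``(Volume3D, MultiClassMask, RelationLabel)``.

    Deterministic given ``spec`` (including its seed). Raises if the
    requested geometry cannot fit in the grid.
    """
    nx, ny, nz = spec.shape
    extent = abs(spec.lateral_offset) + spec.canal_curve_amp + spec.canal_radius + spec.rim_thickness
    if extent >= nx / 2.0 - 1:
        raise ValueError("canal geometry does not fit laterally in the grid")
    if spec.crown_z + spec.crown_semiaxes[2] >= nz or spec.canal_z - spec.canal_radius <= 0:
        raise ValueError("structures do not fit axially in the grid")

    tooth = _tooth_mask(spec)
    r2 = _radial2(spec)
    canal = (r2 <= spec.canal_radius**2) & ~tooth
    rim = (r2 <= (spec.canal_radius + spec.rim_thickness) ** 2) & ~canal & ~tooth

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[tooth] = LABEL_M3
    labels[canal] = LABEL_MC
    if not canal.any():
        raise ValueError("canal fully occluded by the tooth; adjust clearance")

    intensity = np.full(spec.shape, spec.intensity_bone, dtype=np.float64)
    intensity[rim] = spec.intensity_rim
    intensity[tooth] = spec.intensity_tooth
    intensity[canal] = spec.intensity_canal
    rng = np.random.default_rng(spec.seed)
    intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = Volume3D(intensity, spec.spacing, side="left")
    mask = MultiClassMask(labels, spec.spacing)
    return volume, mask, RelationLabel(spec.relation, 1.0)


def relation_oracle(m: MultiClassMask) -> RelationLabel:
    """Geometric ground-truth rule for the buccal/lingual relationship.

    Finds the closest M3–MC voxel pair, then asks on which side of the
    plane spanned by the tooth's main axis (principal axis of the label-1
    voxels) and the mesiodistal direction the canal point lies. The plane
    normal is oriented toward +x, the buccal direction under the left-side
    convention.
    """
    pts_m3 = np.argwhere(m.labels == LABEL_M3).astype(np.float64)
    pts_mc = np.argwhere(m.labels == LABEL_MC).astype(np.float64)
    if len(pts_m3) == 0 or len(pts_mc) == 0:
        raise ValueError("relation_oracle requires both structures present")
    _, point_mc, _ = closest_pair(m)
    centroid = pts_m3.mean(axis=0)
    cov = np.cov((pts_m3 - centroid).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    main_axis = eigvecs[:, np.argmax(eigvals)]
    mesiodistal = np.array([0.0, 1.0, 0.0])
    normal = np.cross(main_axis, mesiodistal)
    if np.linalg.norm(normal) < 1e-9:  # degenerate: tooth axis along y
        normal = np.array([1.0, 0.0, 0.0])
    normal = normal / np.linalg.norm(normal)
    if normal[0] < 0:
        normal = -normal
    side = float(np.dot(normal, np.asarray(point_mc, dtype=np.float64) - centroid))
    return RelationLabel(BUCCAL if side > 0 else LINGUAL, 1.0)


def _jittered_spec(rng: np.random.Generator, relation: str, base: PhantomSpec) -> PhantomSpec:
    """Draw one per-case spec around the defaults (sizes, curvature,
    clearance, noise seed)."""
    return dataclasses.replace(
        base,
        relation=relation,
        crown_semiaxes=(
            base.crown_semiaxes[0] + rng.uniform(-1.0, 1.0),
            base.crown_semiaxes[1] + rng.uniform(-1.0, 1.0),
            base.crown_semiaxes[2] + rng.uniform(-1.0, 1.0),
        ),
        root_length=base.root_length + rng.uniform(-2.0, 2.0),
        canal_radius=float(np.clip(base.canal_radius + rng.uniform(-0.5, 0.5), 1.5, 4.0)),
        canal_z=base.canal_z + rng.uniform(-1.5, 1.5),
        canal_curve_amp=float(np.clip(base.canal_curve_amp + rng.uniform(-1.5, 1.5), 1.0, 6.0)),
        clearance=rng.uniform(0.5, 2.5),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n: int,
    class_balance: float = 0.5,
    seed: int = 0,
    out_dir=None,
    base_spec: PhantomSpec | None = None,
):
    """Generate ``n`` jittered phantoms with an exact class split.

    The number of buccal cases is ``round(n * class_balance)``. If
    ``out_dir`` is given, volume/mask NIfTI pairs are written there along
    with ``manifest.csv`` (columns: volume_path, mask_path, side,
    relation_label); otherwise the cases stay in memory. Returns
    ``(manifest: DataFrame, cases: list[(Volume3D, MultiClassMask,
    RelationLabel)])``. Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least two phantoms")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must lie strictly between 0 and 1")
    base = base_spec or PhantomSpec()
    n_buccal = int(round(n * class_balance))
    relations = [BUCCAL] * n_buccal + [LINGUAL] * (n - n_buccal)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    relations = [relations[i] for i in order]

    rows, cases = [], []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, relation in enumerate(relations):
        spec = _jittered_spec(rng, relation, base)
        volume, mask, label = generate_phantom(spec)
        cases.append((volume, mask, label))
        row = {"case_id": f"phantom_{i:04d}", "side": "left", "relation_label": relation}
        if out_dir is not None:
            vpath = out_dir / f"phantom_{i:04d}_volume.nii.gz"
            mpath = out_dir / f"phantom_{i:04d}_mask.nii.gz"
            write_volume(volume, vpath)
            write_mask(mask, mpath)
            row["volume_path"] = str(vpath)
            row["mask_path"] = str(mpath)
        else:
            row["volume_path"] = ""
            row["mask_path"] = ""
        rows.append(row)
    manifest = pd.DataFrame(
        rows, columns=["case_id", "volume_path", "mask_path", "side", "relation_label"]
    )
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, cases
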