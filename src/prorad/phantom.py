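"""Seeded synthetic head-and-neck CT phantoms.

A phantom is an ellipsoidal head on an elliptic-cylinder neck, with a bony
spine (periodic vertebral bulges), an optional mandible arc, a central
airway, and a subcutaneous fat ring, embedded in air.  Per-seed jitter of
structure sizes and positions provides inter-"patient" variability so that a
cohort of phantoms behaves like a small patient population for range-shift
studies.

Coordinate convention: axes (x, y, z) = (left-right, anterior-posterior,
inferior-superior); +y is posterior, +z superior; 0-based voxel indices with
``world = origin + index * spacing`` at voxel centres.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CtVolume",
    "PhantomSpec",
    "NeckRegion",
    "generate_phantom",
    "generate_cohort",
    "neck_region",
]

HU_MIN, HU_MAX = -1024, 3071


@dataclass(frozen=True)
class CtVolume:
    """A 3-D Hounsfield-unit grid with geometry metadata."""

    hu: np.ndarray  # int16, shape (nx, ny, nz)
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu)
        if hu.ndim != 3:
            raise ValueError("hu must be a 3-D array")
        if hu.dtype != np.int16:
            if not np.all(np.isfinite(hu)):
                raise ValueError("HU values must be finite")
            hu = np.clip(np.rint(hu), HU_MIN, HU_MAX).astype(np.int16)
            object.__setattr__(self, "hu", hu)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical grid size along each axis."""
        return tuple(n * s for n, s in zip(self.hu.shape, self.spacing_mm))

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.hu.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.spacing_mm[axis]

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.hu, affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "CtVolume":
        import nibabel as nib

        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        data = np.asarray(img.dataobj).astype(np.int16)
        return cls(data, spacing, origin)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of a synthetic head-and-neck phantom.

    Lengths are mm; ``hu_values`` must order air < fat < soft < bone.
    ``jitter_fraction`` scales the per-seed random variation of sizes and
    positions; ``noise_sigma_hu`` adds seeded Gaussian texture inside tissue.
    """

    head_radius_mm: float = 80.0
    neck_radius_mm: float = 55.0
    neck_length_mm: float = 100.0
    spine_radius_mm: float = 12.0
    mandible_present: bool = True
    airway_radius_mm: float = 8.0
    fat_ring_thickness_mm: float = 6.0
    posterior_fat_pad_mm: float = 8.0
    n_deep_fat_deposits: int = 3
    hu_values: dict = field(
        default_factory=lambda: {"air": -1000, "fat": -100, "soft": 30, "bone": 700}
    )
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    grid_shape: tuple[int, int, int] = (128, 128, 160)
    noise_sigma_hu: float = 15.0
    jitter_fraction: float = 0.10
    neck_z0_mm: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "head_radius_mm",
            "neck_radius_mm",
            "neck_length_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("spine_radius_mm", "airway_radius_mm", "fat_ring_thickness_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        hv = self.hu_values
        required = {"air", "fat", "soft", "bone"}
        if set(hv) != required:
            raise ValueError(f"hu_values must have keys {sorted(required)}")
        if not (hv["air"] <= hv["fat"] <= hv["soft"] <= hv["bone"]):
            raise ValueError("hu_values must order air <= fat <= soft <= bone")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be strictly positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape too small")

    def spec_hash(self) -> str:
        payload = asdict(self)
        payload["hu_values"] = dict(sorted(self.hu_values.items()))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class NeckRegion:
    """Axial extent of the deformable neck, with a smooth transition zone."""

    z0_mm: float
    z1_mm: float
    transition_mm: float = 20.0
    center_x_mm: float = 0.0
    center_y_mm: float = 0.0


def _check_fits(name: str, lo: float, hi: float, extent: float) -> None:
    if lo < 0 or hi > extent:
        raise ValueError(
            f"phantom structure does not fit in grid along {name}: "
            f"needs [{lo:.1f}, {hi:.1f}] mm within [0, {extent:.1f}] mm"
        )


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> CtVolume:
    """Build one phantom volume; deterministic for fixed ``(spec, seed)``.

    ``seed`` overrides ``spec.seed`` when given.  The per-seed jitter
    multiplies structure radii by ``1 +/- jitter_fraction`` and nudges
    centre positions, so different seeds give distinct anatomies.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(int(seed) % 2**31)
    j = spec.jitter_fraction

    def jit(scale: float = 1.0) -> float:
        return 1.0 + scale * j * rng.uniform(-1.0, 1.0)

    sx, sy, sz = spec.voxel_spacing_mm
    nx, ny, nz = spec.grid_shape
    ex, ey, ez = nx * sx, ny * sy, nz * sz

    head_r = spec.head_radius_mm * jit()
    neck_ra = spec.neck_radius_mm * jit()  # LR semi-axis
    neck_rb = 0.9 * spec.neck_radius_mm * jit()  # AP semi-axis
    neck_len = spec.neck_length_mm * jit()
    spine_r = spec.spine_radius_mm * jit()
    airway_r = spec.airway_radius_mm * jit()
    fat_t = spec.fat_ring_thickness_mm * jit()

    cx = ex / 2 + rng.uniform(-2.0, 2.0)
    cy = ey / 2 + rng.uniform(-2.0, 2.0)
    neck_z0 = spec.neck_z0_mm
    neck_z1 = neck_z0 + neck_len
    head_rz = 1.15 * head_r
    head_cz = neck_z1 + 0.55 * head_rz
    head_rx = 0.85 * head_r
    head_ry = head_r

    _check_fits("z (inferior-superior)", 0.0, head_cz + head_rz, ez)
    _check_fits("x (left-right)", cx - max(head_rx, neck_ra), cx + max(head_rx, neck_ra), ex)
    _check_fits("y (anterior-posterior)", cy - max(head_ry, neck_rb), cy + max(head_ry, neck_rb), ey)

    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    head = (
        ((X - cx) / head_rx) ** 2
        + ((Y - cy) / head_ry) ** 2
        + ((Z - head_cz) / head_rz) ** 2
    ) <= 1.0
    neck_xy = ((X - cx) / neck_ra) ** 2 + ((Y - cy) / neck_rb) ** 2 <= 1.0
    neck = neck_xy & (Z >= neck_z0) & (Z <= neck_z1)
    body = head | neck

    hv = spec.hu_values
    hu = np.full(spec.grid_shape, float(hv["air"]))
    hu[body] = hv["soft"]

    # subcutaneous fat: base ring plus a posterior pad (thicker layer toward
    # the nape), matching the fat distribution of head-and-neck CTs
    if fat_t > 0:
        dist_in = ndimage.distance_transform_edt(body, sampling=(sx, sy, sz))
        rho_xy = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
        posterior = np.clip((Y - cy) / np.maximum(rho_xy, 1e-6), 0.0, 1.0)
        pad = spec.posterior_fat_pad_mm * jit()
        t_eff = fat_t + pad * posterior
        hu[body & (dist_in <= t_eff)] = hv["fat"]

    # deep fat deposits (paraspinal / cheek compartments), jittered per seed
    for _ in range(spec.n_deep_fat_deposits):
        ang = rng.uniform(0.0, 2 * np.pi)
        rad = rng.uniform(0.45, 0.62) * min(neck_ra, neck_rb)
        dcx = cx + rad * np.cos(ang)
        dcy = cy + rad * np.sin(ang)
        dcz = rng.uniform(neck_z0 + 15.0, head_cz - 0.5 * head_rz)
        ax_ = rng.uniform(8.0, 14.0)
        ay_ = rng.uniform(6.0, 11.0)
        az_ = rng.uniform(18.0, 32.0)
        deposit = (
            ((X - dcx) / ax_) ** 2 + ((Y - dcy) / ay_) ** 2 + ((Z - dcz) / az_) ** 2
        ) <= 1.0
        hu[deposit & body] = hv["fat"]

    # spine: posterior bone column with periodic vertebral bulges
    if spine_r > 0:
        spine_y = cy + 0.45 * neck_rb
        bulge = 1.0 + 0.3 * np.clip(np.sin(2 * np.pi * Z / 24.0), 0.0, 1.0)
        spine = (
            ((X - cx) ** 2 + (Y - spine_y) ** 2) <= (spine_r * bulge) ** 2
        ) & (Z <= head_cz) & body
        hu[spine] = hv["bone"]

    # cranial vault: bone shell in the upper head, under the scalp layer
    if spine_r > 0:
        m = np.sqrt(
            ((X - cx) / head_rx) ** 2
            + ((Y - cy) / head_ry) ** 2
            + ((Z - head_cz) / head_rz) ** 2
        )
        skull = (m >= 0.84) & (m <= 0.93) & (Z > head_cz - 0.15 * head_rz) & body
        hu[skull] = hv["bone"]

    # mandible: anterior bone arc in the lower head
    if spec.mandible_present and spine_r > 0:
        mz = head_cz - 0.7 * head_rz
        arc_r = 0.55 * head_r
        tube_r = 5.0 * jit()
        ring = (np.sqrt((X - cx) ** 2 + (Y - cy) ** 2) - arc_r) ** 2 + (Z - mz) ** 2
        mandible = (ring <= tube_r**2) & (Y < cy) & body
        hu[mandible] = hv["bone"]

    # central airway, applied last so it is guaranteed air-valued
    if airway_r > 0:
        aw_y = cy - 0.35 * neck_rb
        airway = (((X - cx) ** 2 + (Y - aw_y) ** 2) <= airway_r**2) & (
            Z <= head_cz
        ) & body
        hu[airway] = hv["air"]
    else:
        airway = np.zeros_like(body)

    if spec.noise_sigma_hu > 0:
        noise = rng.normal(0.0, spec.noise_sigma_hu, size=hu.shape)
        tissue = body & ~airway
        hu[tissue] += noise[tissue]

    return CtVolume(hu, spec.voxel_spacing_mm)


def neck_region(spec: PhantomSpec, volume: CtVolume | None = None) -> NeckRegion:
    """Deformable-region descriptor matching ``generate_phantom`` geometry.

    The centre is the nominal body axis; per-seed jitter moves the true axis
    by a couple of mm, which the deformation operator re-estimates per slice.
    """
    ex = spec.grid_shape[0] * spec.voxel_spacing_mm[0]
    ey = spec.grid_shape[1] * spec.voxel_spacing_mm[1]
    return NeckRegion(
        z0_mm=spec.neck_z0_mm,
        z1_mm=spec.neck_z0_mm + spec.neck_length_mm,
        transition_mm=20.0,
        center_x_mm=ex / 2,
        center_y_mm=ey / 2,
    )


def cohort_member_seed(master_seed: int, index: int) -> int:
    """Stable derived seed for phantom ``index`` of a cohort."""
    ss = np.random.SeedSequence([int(master_seed) % 2**31, int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


def generate_cohort(
    n: int, base_spec: PhantomSpec, seed: int
) -> list[tuple[str, int, CtVolume]]:
    """Generate ``n`` phantoms with ids ``p000, p001, ...`` and derived seeds."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    out = []
    for i in range(int(n)):
        s = cohort_member_seed(seed, i)
        out.append((f"p{i:03d}", s, generate_phantom(base_spec, seed=s)))
    return out
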