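"""Proton radiography simulation by water-equivalent-thickness ray tracing.

A proton radiography (PR) image is a lateral grid of pencil-beam spots shot
through the patient along +x (90 degree gantry); behind the patient each
spot's integral depth dose (IDD) curve is recorded.  Energy loss in tissue
is modelled purely as a residual-range shift: a spot whose ray accumulates
water-equivalent thickness ``w`` measures the pristine Bragg curve shifted
proximally by ``w``.  Lateral heterogeneity blurs the measured curve; this
"range mixing" is modelled as a Gaussian-weighted mixture (sigma = 3.5 mm)
of the shifted curves in the spot's neighbourhood, which reproduces the
characteristic bimodal IDDs at tissue interfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import erfc

from .calibration import CalibrationCurve, hu_to_rsp
from .phantom import CtVolume

__all__ = [
    "BeamConfig",
    "BeamGeometry",
    "IddCurve",
    "PrImage",
    "Ray",
    "apply_range_mixing",
    "compute_wet",
    "pristine_idd",
    "simulate_pr",
    "spot_idd_from_wet",
]


@dataclass(frozen=True)
class BeamConfig:
    """Beam and field parameters for a PR acquisition.

    ``water_range_r0_mm`` is the residual range in water of the 210 MeV
    beam.  ``mixing_sigma_mm`` is the lateral Gaussian range-mixing kernel.
    ``fine_pitch_mm = None`` resolves at simulation time to
    ``max(in-plane voxel spacing, 1 mm)``.
    """

    energy_label: str = "210 MeV"
    water_range_r0_mm: float = 279.0
    field_size_mm: tuple[float, float] = (260.0, 260.0)
    spot_spacing_mm: float = 1.0
    mixing_sigma_mm: float = 3.5
    depth_max_mm: float = 340.0
    depth_step_mm: float = 1.0
    fine_pitch_mm: float | None = None

    def __post_init__(self) -> None:
        if self.spot_spacing_mm <= 0:
            raise ValueError("spot spacing must be > 0")
        if self.mixing_sigma_mm < 0:
            raise ValueError("mixing sigma must be >= 0")
        if not (0 < self.water_range_r0_mm < self.depth_max_mm):
            raise ValueError("water range r0 must lie inside the depth grid")

    @classmethod
    def desk(cls, **kw) -> "BeamConfig":
        """Desk-scale preset: 128x128 mm field at 4 mm spot spacing."""
        kw.setdefault("field_size_mm", (128.0, 128.0))
        kw.setdefault("spot_spacing_mm", 4.0)
        return cls(**kw)

    @property
    def depth_grid(self) -> np.ndarray:
        n = int(round(self.depth_max_mm / self.depth_step_mm)) + 1
        return np.arange(n) * self.depth_step_mm

    def n_spots(self) -> tuple[int, int]:
        w, h = self.field_size_mm
        s = self.spot_spacing_mm
        return (int(np.floor(w / s)) + 1, int(np.floor(h / s)) + 1)


@dataclass(frozen=True)
class IddCurve:
    """Integral depth dose versus water-equivalent depth (uniform grid)."""

    z: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        d = np.asarray(self.dose, dtype=float)
        if z.shape != d.shape or z.ndim != 1:
            raise ValueError("z and dose must be matching 1-D arrays")
        if np.any(d < -1e-12):
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "dose", np.maximum(d, 0.0))

    @property
    def peak_depth_mm(self) -> float:
        return float(self.z[int(np.argmax(self.dose))])


@dataclass(frozen=True)
class Ray:
    """A straight ray through the volume (unit direction, world mm)."""

    entry_mm: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("ray direction must be non-zero")
        object.__setattr__(self, "direction", tuple(d / n))
        object.__setattr__(self, "entry_mm", tuple(float(v) for v in self.entry_mm))


@dataclass(frozen=True)
class BeamGeometry:
    """Spot coordinate axes of a PR field; rays travel along +x.

    ``u_mm`` spans the inferior-superior axis (z), ``v_mm`` the
    anterior-posterior axis (y).  ``shift_ap_mm``/``shift_is_mm`` translate
    every ray entry point rigidly while spot labels stay put, which is how
    rigid setup errors enter the simulation.
    """

    u_mm: np.ndarray
    v_mm: np.ndarray
    shift_ap_mm: float = 0.0
    shift_is_mm: float = 0.0

    def translated(self, d_ap_mm: float, d_is_mm: float) -> "BeamGeometry":
        return replace(
            self,
            shift_ap_mm=self.shift_ap_mm + float(d_ap_mm),
            shift_is_mm=self.shift_is_mm + float(d_is_mm),
        )


def pristine_idd(cfg: BeamConfig) -> IddCurve:
    """Analytic pristine Bragg curve in water, peak-normalized to 1.

    Parametric plateau + Gaussian peak with an erfc distal cutoff: a gently
    rising entrance plateau, a strictly unimodal peak at ``r0``, and a distal
    falloff of a few mm.  A stand-in for a measured/Monte-Carlo IDD; the
    range-shift analysis only relies on its smooth unimodal shape.
    """
    z = cfg.depth_grid
    r0 = cfg.water_range_r0_mm
    plateau = 0.25 + 0.10 * (z / r0) ** 2
    peak = 0.75 * np.exp(-((z - r0) ** 2) / (2 * 2.5**2))
    distal = 0.5 * erfc((z - r0 - 3.0) / 2.0)
    dose = (plateau + peak) * distal
    return IddCurve(z, dose / dose.max())


def compute_wet(ct: CtVolume, curve: CalibrationCurve, ray: Ray) -> float:
    """Water-equivalent thickness along a ray, by exact voxel traversal.

    Siddon-style: the ray is intersected with the voxel-boundary planes of
    all three axes; each traversed voxel contributes
    ``rsp(voxel) * intersection_length``.  Returns 0.0 for a ray that misses
    the grid.
    """
    p0 = np.asarray(ray.entry_mm)
    d = np.asarray(ray.direction)
    origin = np.asarray(ct.origin_mm)
    spacing = np.asarray(ct.spacing_mm)
    shape = np.asarray(ct.hu.shape)
    lo, hi = origin, origin + shape * spacing

    # clip the ray to the grid bounding box (slab method)
    tmin, tmax = 0.0, np.inf
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            if not (lo[ax] <= p0[ax] <= hi[ax]):
                return 0.0
        else:
            t1 = (lo[ax] - p0[ax]) / d[ax]
            t2 = (hi[ax] - p0[ax]) / d[ax]
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
    if tmax <= tmin:
        return 0.0

    # all boundary-crossing parameters within [tmin, tmax]
    ts = [np.asarray([tmin, tmax])]
    for ax in range(3):
        if abs(d[ax]) > 1e-12:
            planes = lo[ax] + spacing[ax] * np.arange(shape[ax] + 1)
            t = (planes - p0[ax]) / d[ax]
            ts.append(t[(t > tmin) & (t < tmax)])
    t_all = np.unique(np.concatenate(ts))
    seg = np.diff(t_all)
    mid = p0[None, :] + 0.5 * (t_all[:-1] + t_all[1:])[:, None] * d[None, :]
    idx = np.floor((mid - origin) / spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    if not np.any(inside):
        return 0.0
    idx = idx[inside]
    hu = ct.hu[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite HU along ray path")
    rsp = hu_to_rsp(curve, hu)
    return float(np.sum(rsp * seg[inside]))


def spot_idd_from_wet(w: float, pristine: IddCurve) -> IddCurve:
    """Shift the pristine curve proximally by WET ``w`` (residual range).

    ``dose_out(z) = pristine(z + w)`` by linear interpolation, zero beyond
    the curve's support.  A ``w`` beyond the full depth grid yields an
    all-zero curve and a "shoot-through lost" warning.
    """
    if w < 0:
        raise ValueError("WET must be >= 0")
    z = pristine.z
    dose = np.interp(z + w, z, pristine.dose, left=0.0, right=0.0)
    if dose.max() <= 0.0:
        warnings.warn("shoot-through lost: WET exceeds the depth grid", stacklevel=2)
    return IddCurve(z, dose)


def _shifted_curve_matrix(pristine_dose: np.ndarray, n_shift: int) -> np.ndarray:
    """Rows ``k`` = pristine shifted proximally by ``k`` grid steps."""
    nz = pristine_dose.size
    padded = np.concatenate([pristine_dose, np.zeros(n_shift + 1)])
    idx = np.arange(nz)[None, :] + np.arange(n_shift + 1)[:, None]
    return padded[idx]


def _mixed_spot_curves(
    fine_wet: np.ndarray,
    fine_pitch_mm: float,
    spot_rows: np.ndarray,
    spot_cols: np.ndarray,
    cfg: BeamConfig,
    pristine: IddCurve,
) -> np.ndarray:
    """Gaussian range mixing, vectorized over all spots.

    Because the shifted pristine curve is piecewise linear on its own depth
    grid, linearly distributing each member's WET over the two neighbouring
    integer grid shifts and mixing the integer-shifted curves is *exact* —
    it equals the Gaussian-weighted sum of the individually shifted curves.
    Returns an array of shape ``(n_spots, nz)``.
    """
    sigma = cfg.mixing_sigma_mm
    dz = cfg.depth_step_mm
    nz = pristine.z.size
    n_spots = spot_rows.size

    if sigma == 0.0:
        w = fine_wet[spot_rows, spot_cols]
        i0 = np.floor(w / dz).astype(int)
        f = w / dz - i0
        mat = _shifted_curve_matrix(pristine.dose, int(np.ceil(fine_wet.max() / dz)) + 1)
        return (1 - f)[:, None] * mat[i0] + f[:, None] * mat[i0 + 1]

    reach = int(np.ceil(3.0 * sigma / fine_pitch_mm))
    offs = np.arange(-reach, reach + 1)
    dv, du = np.meshgrid(offs, offs, indexing="ij")
    dist2 = (dv**2 + du**2) * fine_pitch_mm**2
    keep = dist2 <= (3.0 * sigma) ** 2
    dv, du = dv[keep], du[keep]
    wgt = np.exp(-dist2[keep] / (2.0 * sigma**2))
    if dv.size == 0:
        raise ValueError("empty mixing neighbourhood")
    wgt = wgt / wgt.sum()

    nrow, ncol = fine_wet.shape
    rows = np.clip(spot_rows[:, None] + dv[None, :], 0, nrow - 1)
    cols = np.clip(spot_cols[:, None] + du[None, :], 0, ncol - 1)
    w_members = fine_wet[rows, cols]  # (n_spots, n_members)

    n_shift = int(np.ceil(w_members.max() / dz)) + 1
    i0 = np.floor(w_members / dz).astype(int)
    f = w_members / dz - i0
    hist = np.zeros((n_spots, n_shift + 2))
    spot_idx = np.broadcast_to(np.arange(n_spots)[:, None], i0.shape)
    wgt_b = np.broadcast_to(wgt[None, :], i0.shape)
    np.add.at(hist, (spot_idx, i0), wgt_b * (1.0 - f))
    np.add.at(hist, (spot_idx, i0 + 1), wgt_b * f)

    mat = _shifted_curve_matrix(pristine.dose, n_shift + 1)  # (n_shift+2, nz)
    return hist @ mat


def apply_range_mixing(
    fine_wet: np.ndarray,
    fine_u_mm: np.ndarray,
    fine_v_mm: np.ndarray,
    spot_u_mm: np.ndarray,
    spot_v_mm: np.ndarray,
    cfg: BeamConfig,
    pristine: IddCurve | None = None,
) -> list[IddCurve]:
    """Mixed IDD curve per spot from a fine lateral WET field.

    ``fine_wet`` is indexed ``[i_v, i_u]``; spots must lie on fine-grid
    nodes (they do whenever the spot spacing is a multiple of the fine
    pitch).  ``sigma = 0`` degenerates to the unmixed per-spot curve.
    """
    pristine = pristine or pristine_idd(cfg)
    pitch = float(fine_u_mm[1] - fine_u_mm[0]) if fine_u_mm.size > 1 else 1.0
    rows = np.rint((spot_v_mm[:, None] - fine_v_mm[0]) / pitch).astype(int)
    cols = np.rint((spot_u_mm[None, :] - fine_u_mm[0]) / pitch).astype(int)
    rows = np.clip(rows, 0, fine_wet.shape[0] - 1)
    cols = np.clip(cols, 0, fine_wet.shape[1] - 1)
    rr = np.broadcast_to(rows, (spot_v_mm.size, spot_u_mm.size)).ravel()
    cc = np.broadcast_to(cols, (spot_v_mm.size, spot_u_mm.size)).ravel()
    curves = _mixed_spot_curves(fine_wet, pitch, rr, cc, cfg, pristine)
    return [IddCurve(pristine.z, d) for d in curves]


@dataclass(frozen=True)
class PrImage:
    """A simulated proton radiography image.

    ``wet_mm[i_v, i_u]`` is the per-spot WET; the per-spot (range-mixed) IDD
    curves are reconstructable on demand from the stored fine WET field, the
    beam config and the pristine curve (``mixed_idds``).
    """

    spot_u_mm: np.ndarray  # (n_u,)  inferior-superior
    spot_v_mm: np.ndarray  # (n_v,)  anterior-posterior
    wet_mm: np.ndarray  # (n_v, n_u)
    fine_u_mm: np.ndarray
    fine_v_mm: np.ndarray
    fine_wet_mm: np.ndarray  # (n_fine_v, n_fine_u)
    cfg: BeamConfig

    def __post_init__(self) -> None:
        if np.any(self.wet_mm < 0):
            raise ValueError("WET must be non-negative")
        if self.wet_mm.shape != (self.spot_v_mm.size, self.spot_u_mm.size):
            raise ValueError("wet grid does not match spot axes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.wet_mm.shape

    def pristine(self) -> IddCurve:
        return pristine_idd(self.cfg)

    def mixed_idds(self) -> np.ndarray:
        """Range-mixed IDD stack, shape ``(n_v, n_u, nz)``."""
        pristine = self.pristine()
        pitch = float(self.cfg.fine_pitch_mm or 1.0)
        if self.fine_u_mm.size > 1:
            pitch = float(self.fine_u_mm[1] - self.fine_u_mm[0])
        rows = np.rint((self.spot_v_mm - self.fine_v_mm[0]) / pitch).astype(int)
        cols = np.rint((self.spot_u_mm - self.fine_u_mm[0]) / pitch).astype(int)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        curves = _mixed_spot_curves(
            self.fine_wet_mm, pitch, rr.ravel(), cc.ravel(), self.cfg, pristine
        )
        return curves.reshape(self.shape + (pristine.z.size,))

    def save_h5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("spots/u", data=self.spot_u_mm)
            f.create_dataset("spots/v", data=self.spot_v_mm)
            f.create_dataset("wet", data=self.wet_mm.astype(np.float32))
            f.create_dataset("fine/u", data=self.fine_u_mm)
            f.create_dataset("fine/v", data=self.fine_v_mm)
            f.create_dataset("fine/wet", data=self.fine_wet_mm.astype(np.float32))
            for k, v in vars(self.cfg).items():
                f.attrs[k] = "none" if v is None else v

    @classmethod
    def load_h5(cls, path: str | Path) -> "PrImage":
        import h5py

        with h5py.File(path, "r") as f:
            attrs = {k: (None if (isinstance(v, str) and v == "none") else v) for k, v in f.attrs.items()}
            attrs["field_size_mm"] = tuple(attrs["field_size_mm"])
            attrs["energy_label"] = str(attrs["energy_label"])
            cfg = BeamConfig(**attrs)
            return cls(
                spot_u_mm=f["spots/u"][:],
                spot_v_mm=f["spots/v"][:],
                wet_mm=f["wet"][:].astype(float),
                fine_u_mm=f["fine/u"][:],
                fine_v_mm=f["fine/v"][:],
                fine_wet_mm=f["fine/wet"][:].astype(float),
                cfg=cfg,
            )


def _rsp_lut(curve: CalibrationCurve) -> np.ndarray:
    hu = np.arange(-1024, 3072, dtype=float)
    return hu_to_rsp(curve, hu)


def default_geometry(ct: CtVolume, cfg: BeamConfig) -> BeamGeometry:
    """Field centred on the volume's (y, z) centre; rays along +x."""
    n_v, n_u = cfg.n_spots()  # field_size_mm = (v extent, u extent)
    s = cfg.spot_spacing_mm
    _, ey, ez = ct.extent_mm
    v = ey / 2 + (np.arange(n_v) - (n_v - 1) / 2) * s
    u = ez / 2 + (np.arange(n_u) - (n_u - 1) / 2) * s
    return BeamGeometry(u_mm=u, v_mm=v)


def simulate_pr(
    ct: CtVolume,
    curve: CalibrationCurve,
    cfg: BeamConfig,
    shift: tuple[float, float] = (0.0, 0.0),
    geometry: BeamGeometry | None = None,
) -> PrImage:
    """Simulate a PR image: per-spot WET and (lazily) range-mixed IDDs.

    Rays are cast along +x for every spot and for a fine lateral sub-grid
    (for range mixing) after applying the rigid setup ``shift = (d_ap,
    d_is)`` to all ray entry points.  For axis-aligned rays the Siddon
    traversal reduces to the RSP line integral of the voxel column
    containing the ray, which is what this fast path computes.
    """
    geom = geometry or default_geometry(ct, cfg)
    geom = geom.translated(*shift)
    sx, sy, sz = ct.spacing_mm
    pitch = cfg.fine_pitch_mm or max(sy, 1.0)

    lut = _rsp_lut(curve)
    rsp = lut[ct.hu.astype(np.int32) + 1024]
    proj = rsp.sum(axis=0) * sx  # (ny, nz): WET of each (y, z) voxel column

    # margin rounded to the fine pitch so spots land exactly on fine nodes
    margin = np.ceil(3.0 * cfg.mixing_sigma_mm / pitch) * pitch
    n_fv = int(np.ceil((geom.v_mm[-1] - geom.v_mm[0] + 2 * margin) / pitch)) + 1
    n_fu = int(np.ceil((geom.u_mm[-1] - geom.u_mm[0] + 2 * margin) / pitch)) + 1
    fine_v = geom.v_mm[0] - margin + np.arange(n_fv) * pitch
    fine_u = geom.u_mm[0] - margin + np.arange(n_fu) * pitch

    # patient-frame sampling positions include the rigid setup shift
    y_pos = fine_v + geom.shift_ap_mm
    z_pos = fine_u + geom.shift_is_mm
    jy = np.floor((y_pos - ct.origin_mm[1]) / sy).astype(int)
    kz = np.floor((z_pos - ct.origin_mm[2]) / sz).astype(int)
    ok_y = (jy >= 0) & (jy < proj.shape[0])
    ok_z = (kz >= 0) & (kz < proj.shape[1])
    fine_wet = np.zeros((n_fv, n_fu))
    fine_wet[np.ix_(ok_y, ok_z)] = proj[np.ix_(jy[ok_y], kz[ok_z])]

    iv = np.rint((geom.v_mm - fine_v[0]) / pitch).astype(int)
    iu = np.rint((geom.u_mm - fine_u[0]) / pitch).astype(int)
    wet = fine_wet[np.ix_(iv, iu)]

    return PrImage(
        spot_u_mm=geom.u_mm.copy(),
        spot_v_mm=geom.v_mm.copy(),
        wet_mm=wet,
        fine_u_mm=fine_u,
        fine_v_mm=fine_v,
        fine_wet_mm=fine_wet,
        cfg=cfg,
    )
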