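"""HU-to-relative-stopping-power calibration curves and tissue perturbations.

Proton range prediction rests on a calibration curve (CC) mapping CT
Hounsfield units to relative stopping power (RSP).  Errors in the CC — a
mis-assigned density for fat, soft tissue or bone — translate directly into
water-equivalent-thickness (and hence range) errors.  This module houses the
piecewise-linear curve, a four-band HU tissue classification, and the
multiplicative density perturbation model ``rsp_mod = rsp * (1 + p)`` applied
per tissue band.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CalibrationCurve",
    "TissueBands",
    "TissuePerturbation",
    "classify_tissue",
    "default_curve",
    "hu_to_rsp",
    "perturb_curve",
]

#: Default control points: air, fat, water, soft tissue, bone, dense bone.
_DEFAULT_POINTS = (
    (-1000.0, 0.00),
    (-100.0, 0.95),
    (0.0, 1.00),
    (30.0, 1.02),
    (700.0, 1.40),
    (1500.0, 1.90),
)


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear HU -> RSP map, clamped outside the control range.

    Parameters
    ----------
    hu
        Strictly increasing control-point Hounsfield units.
    rsp
        Non-negative relative stopping power at each control point.
    """

    hu: np.ndarray
    rsp: np.ndarray

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        rsp = np.asarray(self.rsp, dtype=float)
        if hu.ndim != 1 or hu.shape != rsp.shape:
            raise ValueError("hu and rsp must be 1-D arrays of equal length")
        if hu.size < 2:
            raise ValueError("need at least two control points")
        if not np.all(np.diff(hu) > 0):
            raise ValueError("control-point HU must be strictly increasing")
        if np.any(rsp < 0):
            raise ValueError("relative stopping power must be >= 0")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "rsp", rsp)

    def __call__(self, h: np.ndarray | float) -> np.ndarray | float:
        return hu_to_rsp(self, h)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["hu", "rsp"])
            for h, r in zip(self.hu, self.rsp):
                w.writerow([f"{h:g}", f"{r:g}"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        hu, rsp = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                hu.append(float(row["hu"]))
                rsp.append(float(row["rsp"]))
        return cls(np.asarray(hu), np.asarray(rsp))


@dataclass(frozen=True)
class TissueBands:
    """Half-open HU bands classifying voxels as air / fat / soft / bone.

    A value ``h`` is air if ``h < fat_lo``, fat in ``[fat_lo, soft_lo)``,
    soft in ``[soft_lo, bone_lo)`` and bone for ``h >= bone_lo``.
    """

    fat_lo: float = -200.0
    soft_lo: float = -20.0
    bone_lo: float = 120.0

    def __post_init__(self) -> None:
        if not (self.fat_lo < self.soft_lo < self.bone_lo):
            raise ValueError("tissue band edges must be increasing")


@dataclass(frozen=True)
class TissuePerturbation:
    """Fractional density perturbation per tissue band (air is never touched)."""

    p_fat: float = 0.0
    p_soft: float = 0.0
    p_bone: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {"p_fat": self.p_fat, "p_soft": self.p_soft, "p_bone": self.p_bone}

    def inverse(self) -> "TissuePerturbation":
        """Perturbation that undoes this one: p' = -p / (1 + p) per band."""
        return TissuePerturbation(
            p_fat=-self.p_fat / (1.0 + self.p_fat),
            p_soft=-self.p_soft / (1.0 + self.p_soft),
            p_bone=-self.p_bone / (1.0 + self.p_bone),
        )


def default_curve() -> CalibrationCurve:
    """A monotone six-point clinical-style curve anchored at air and water."""
    pts = np.asarray(_DEFAULT_POINTS)
    return CalibrationCurve(pts[:, 0], pts[:, 1])


def hu_to_rsp(curve: CalibrationCurve, h: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the curve at HU value(s) ``h`` (linear, clamped at the ends)."""
    h_arr = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h_arr)):
        raise ValueError("non-finite HU value")
    out = np.interp(h_arr, curve.hu, curve.rsp)
    return float(out) if np.isscalar(h) or h_arr.ndim == 0 else out


def classify_tissue(h: float | np.ndarray, bands: TissueBands | None = None) -> str | np.ndarray:
    """Classify HU into one of ``{"air", "fat", "soft", "bone"}``."""
    bands = bands or TissueBands()
    h_arr = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h_arr)):
        raise ValueError("non-finite HU value")
    labels = np.asarray(["air", "fat", "soft", "bone"])
    idx = np.digitize(h_arr, [bands.fat_lo, bands.soft_lo, bands.bone_lo])
    out = labels[idx]
    return str(out) if np.isscalar(h) or h_arr.ndim == 0 else out


def perturb_curve(
    curve: CalibrationCurve,
    pert: TissuePerturbation,
    bands: TissueBands | None = None,
) -> CalibrationCurve:
    """Apply the density perturbation model per tissue band.

    Every control point whose HU falls in the fat/soft/bone band has its RSP
    multiplied by ``(1 + p_band)``; air-band points are unchanged.
    """
    bands = bands or TissueBands()
    for name, p in pert.as_dict().items():
        if not np.isfinite(p):
            raise ValueError(f"non-finite perturbation {name}")
    factor = np.asarray(
        [1.0, 1.0 + pert.p_fat, 1.0 + pert.p_soft, 1.0 + pert.p_bone]
    )
    idx = np.digitize(curve.hu, [bands.fat_lo, bands.soft_lo, bands.bone_lo])
    rsp = curve.rsp * factor[idx]
    if np.any(rsp < 0):
        raise ValueError("perturbation drives relative stopping power below zero")
    return CalibrationCurve(curve.hu, rsp)
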