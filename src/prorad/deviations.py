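"""Treatment-deviation taxonomy, sampling, application, and ground truth.

Eight primary deviation categories cover the clinically relevant sources of
proton range error in head-and-neck treatments: rigid setup shifts along the
anterior-posterior (AP) and inferior-superior (IS) axes, calibration-curve
density errors per tissue (BONE, FAT, SOFT), neck anatomy changes mimicking
weight gain/loss (EXP, CONT), and a NONREL class for deviations below
clinical relevance.  Single categories plus every pairwise combination —
excluding NONREL pairs and the mutually exclusive CONT & EXP — give the
28-class taxonomy used by the classifier.

Magnitudes mirror the study conditions: setup shifts of 2-4 mm (truncated
normal, random sign), neck deformations of +/-2 to +/-12 mm, density
perturbations of +/-{3,4,5}% for fat and soft tissue and +/-{7,9,11}% for
bone.  Small always-on "background" nuisances (<=1 mm setup, <=2% per
tissue) keep non-deviation structure in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage

from .calibration import TissuePerturbation
from .phantom import CtVolume, NeckRegion
from .pr_sim import BeamGeometry

__all__ = [
    "CATEGORIES",
    "DeviationSpec",
    "LabelSet",
    "RelevanceThresholds",
    "SamplingConfig",
    "apply_setup_shift",
    "assign_labels",
    "deform_anatomy",
    "enumerate_classes",
    "sample_deviation",
]

CATEGORIES = ("AP", "BONE", "CONT", "EXP", "FAT", "IS", "NONREL", "SOFT")

#: Perturbation magnitude levels per tissue category.
BONE_LEVELS = (0.07, 0.09, 0.11)
FATSOFT_LEVELS = (0.03, 0.04, 0.05)


def enumerate_classes() -> list[str]:
    """Canonical ordered list of the 28 deviation classes.

    Eight single categories plus every unordered pair of distinct
    categories, excluding pairs containing NONREL and the mutually
    exclusive CONT & EXP pair.  Pair members and the list itself are
    alphabetically ordered; pair ids read ``"A & B"``.
    """
    singles = [(c,) for c in CATEGORIES]
    pairs = [
        p
        for p in combinations(sorted(CATEGORIES), 2)
        if "NONREL" not in p and p != ("CONT", "EXP")
    ]
    ordered = sorted(singles + pairs)
    return [" & ".join(members) for members in ordered]


def class_members(class_id: str) -> tuple[str, ...]:
    members = tuple(class_id.split(" & "))
    if class_id not in enumerate_classes():
        raise ValueError(f"unknown deviation class: {class_id!r}")
    return members


@dataclass(frozen=True)
class DeviationSpec:
    """One sample's ground-truth deviation magnitudes.

    ``deform_mm > 0`` is neck expansion, ``< 0`` contraction.  ``pert`` holds
    the per-tissue calibration-curve perturbations (main + background).
    """

    d_ap_mm: float = 0.0
    d_is_mm: float = 0.0
    deform_mm: float = 0.0
    pert: TissuePerturbation = field(default_factory=TissuePerturbation)
    background: bool = False

    def __post_init__(self) -> None:
        vals = [self.d_ap_mm, self.d_is_mm, self.deform_mm]
        vals += list(self.pert.as_dict().values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("deviation magnitudes must be finite")

    def as_dict(self) -> dict:
        return {
            "d_ap_mm": self.d_ap_mm,
            "d_is_mm": self.d_is_mm,
            "deform_mm": self.deform_mm,
            **self.pert.as_dict(),
            "background": self.background,
        }


@dataclass(frozen=True)
class LabelSet:
    """Ground-truth classes of a sample as a subset of the 28-class taxonomy."""

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("LabelSet must be non-empty")
        taxonomy = set(enumerate_classes())
        for c in self.classes:
            if c not in taxonomy:
                raise ValueError(f"unknown class {c!r}")
        if "NONREL" in self.classes and len(self.classes) > 1:
            raise ValueError("NONREL must be the only class when present")
        object.__setattr__(self, "classes", tuple(sorted(self.classes)))

    def vector(self) -> np.ndarray:
        order = enumerate_classes()
        v = np.zeros(len(order), dtype=np.int8)
        for c in self.classes:
            v[order.index(c)] = 1
        return v


@dataclass(frozen=True)
class RelevanceThresholds:
    """Magnitudes above which a deviation component is clinically relevant."""

    setup_mm: float = 1.0
    cc_fraction: float = 0.02
    deform_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.setup_mm, self.cc_fraction, self.deform_mm) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class SamplingConfig:
    """How deviation magnitudes are drawn for each category."""

    setup_range_mm: tuple[float, float] = (2.0, 4.0)
    setup_sigma_mm: float = 1.5
    deform_min_mm: float = 2.0
    deform_max_mm: float = 12.0
    continuous_deform: bool = False
    background: bool = True
    background_setup_mm: float = 1.0
    background_cc_fraction: float = 0.02


def _setup_magnitude(rng: np.random.Generator, cfg: SamplingConfig) -> float:
    lo, hi = cfg.setup_range_mm
    while True:  # truncated |N(0, sigma)|
        m = abs(rng.normal(0.0, cfg.setup_sigma_mm))
        if lo <= m <= hi:
            return m


def _sign(rng: np.random.Generator) -> float:
    return 1.0 if rng.random() < 0.5 else -1.0


def sample_deviation(
    class_id: str,
    rng: np.random.Generator,
    cfg: SamplingConfig | None = None,
) -> DeviationSpec:
    """Draw deviation magnitudes for a taxonomy class.

    Background nuisances are added only on components the class does not
    already use, so the labelling round trip
    ``assign_labels(sample_deviation(c)) == c`` holds for every seed.
    """
    cfg = cfg or SamplingConfig()
    members = class_members(class_id)

    d_ap = d_is = deform = 0.0
    p = {"fat": 0.0, "soft": 0.0, "bone": 0.0}
    for m in members:
        if m == "AP":
            d_ap = _sign(rng) * _setup_magnitude(rng, cfg)
        elif m == "IS":
            d_is = _sign(rng) * _setup_magnitude(rng, cfg)
        elif m == "EXP":
            deform = _draw_deform(rng, cfg)
        elif m == "CONT":
            deform = -_draw_deform(rng, cfg)
        elif m == "BONE":
            p["bone"] = _sign(rng) * float(rng.choice(BONE_LEVELS))
        elif m == "FAT":
            p["fat"] = _sign(rng) * float(rng.choice(FATSOFT_LEVELS))
        elif m == "SOFT":
            p["soft"] = _sign(rng) * float(rng.choice(FATSOFT_LEVELS))
        # NONREL: nothing structured

    if cfg.background:
        b_mm, b_cc = cfg.background_setup_mm, cfg.background_cc_fraction
        if "AP" not in members:
            d_ap = rng.uniform(-b_mm, b_mm)
        if "IS" not in members:
            d_is = rng.uniform(-b_mm, b_mm)
        for tissue, cat in (("fat", "FAT"), ("soft", "SOFT"), ("bone", "BONE")):
            if cat not in members:
                p[tissue] = rng.uniform(-b_cc, b_cc)

    return DeviationSpec(
        d_ap_mm=d_ap,
        d_is_mm=d_is,
        deform_mm=deform,
        pert=TissuePerturbation(p_fat=p["fat"], p_soft=p["soft"], p_bone=p["bone"]),
        background=cfg.background,
    )


def _draw_deform(rng: np.random.Generator, cfg: SamplingConfig) -> float:
    if cfg.continuous_deform:
        return rng.uniform(cfg.deform_min_mm, cfg.deform_max_mm)
    choices = np.arange(cfg.deform_min_mm, cfg.deform_max_mm + 1e-9, 2.0)
    return float(rng.choice(choices))


def apply_setup_shift(
    geometry: BeamGeometry, d_ap_mm: float, d_is_mm: float
) -> BeamGeometry:
    """Rigidly translate all ray entry points; spot labels stay paired."""
    if not np.all(np.isfinite([d_ap_mm, d_is_mm])):
        raise ValueError("setup shifts must be finite")
    return geometry.translated(d_ap_mm, d_is_mm)


def assign_labels(
    spec: DeviationSpec, thr: RelevanceThresholds | None = None
) -> LabelSet:
    """Ground-truth labelling: categories whose magnitude exceeds threshold.

    At most two supra-threshold categories map onto a taxonomy class; more
    is an error (outside the taxonomy).  No supra-threshold category maps
    to NONREL.
    """
    thr = thr or RelevanceThresholds()
    cats = []
    if abs(spec.d_ap_mm) > thr.setup_mm:
        cats.append("AP")
    if abs(spec.d_is_mm) > thr.setup_mm:
        cats.append("IS")
    if spec.deform_mm > thr.deform_mm:
        cats.append("EXP")
    if spec.deform_mm < -thr.deform_mm:
        cats.append("CONT")
    if abs(spec.pert.p_bone) > thr.cc_fraction:
        cats.append("BONE")
    if abs(spec.pert.p_fat) > thr.cc_fraction:
        cats.append("FAT")
    if abs(spec.pert.p_soft) > thr.cc_fraction:
        cats.append("SOFT")
    if not cats:
        return LabelSet(("NONREL",))
    if len(cats) > 2:
        raise ValueError(
            f"{len(cats)} supra-threshold categories {cats}: outside the 28-class taxonomy"
        )
    return LabelSet((" & ".join(sorted(cats)),))


# ---------------------------------------------------------------------------
# anatomy deformation


def _slice_radius_profile(
    mask: np.ndarray,
    cx: float,
    cy: float,
    spacing: tuple[float, float],
    n_theta: int = 256,
) -> np.ndarray:
    """External contour radius R(theta) of a star-shaped body mask, in mm."""
    sx, sy = spacing
    r_max = float(np.hypot(mask.shape[0] * sx, mask.shape[1] * sy)) / 2
    r = np.arange(0.0, r_max, min(sx, sy) / 2)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    xs = (cx + np.outer(np.cos(theta), r)) / sx - 0.5
    ys = (cy + np.outer(np.sin(theta), r)) / sy - 0.5
    occ = ndimage.map_coordinates(
        mask.astype(np.uint8), [xs, ys], order=0, mode="constant"
    )
    # outermost occupied sample per angle
    any_occ = occ.any(axis=1)
    last = occ.shape[1] - 1 - np.argmax(occ[:, ::-1], axis=1)
    prof = np.where(any_occ, r[np.clip(last, 0, r.size - 1)], 0.0)
    return prof


def deform_anatomy(
    ct: CtVolume,
    deform_mm: float,
    region: NeckRegion,
    body_threshold_hu: float = -300.0,
    protect_margin_mm: float = 15.0,
    min_core_radius_mm: float = 24.0,
) -> CtVolume:
    """Expand or contract the external neck contour radially by ``deform_mm``.

    Per axial slice inside the region, the body boundary at radius R(theta)
    moves to R + a(z), where the amplitude a(z) ramps with a cosine from 0
    at the region's axial edges to ``deform_mm`` in its interior.  The
    mapping is the identity inside a protected core (interior structures —
    spine, airway — stay put) and radially stretches/compresses only the
    outer ``protect_margin_mm`` of tissue, so new tissue on expansion takes
    the fat/soft HU of the subcutaneous layer.  The head region and
    everything outside the neck z-range are untouched.
    """
    if abs(deform_mm) > 15:
        raise ValueError("|deform_mm| must be <= 15")
    if deform_mm == 0:
        return ct
    sx, sy, sz = ct.spacing_mm
    z = ct.voxel_centers(2)
    span = region.z1_mm - region.z0_mm
    t = min(region.transition_mm, span / 2)

    # cosine ramp: 0 at region edges, full amplitude in the interior
    amp = np.zeros_like(z)
    inside = (z > region.z0_mm) & (z < region.z1_mm)
    rise = inside & (z < region.z0_mm + t)
    fall = inside & (z > region.z1_mm - t)
    amp[inside] = deform_mm
    amp[rise] = deform_mm * 0.5 * (1 - np.cos(np.pi * (z[rise] - region.z0_mm) / t))
    amp[fall] = deform_mm * 0.5 * (1 - np.cos(np.pi * (region.z1_mm - z[fall]) / t))

    nx, ny = ct.hu.shape[:2]
    gx = (np.arange(nx) + 0.5) * sx
    gy = (np.arange(ny) + 0.5) * sy
    out = np.array(ct.hu, dtype=np.float32)
    air_hu = float(ct.hu.min())

    for k in np.nonzero(np.abs(amp) > 1e-6)[0]:
        a = float(amp[k])
        sl = ct.hu[:, :, k].astype(np.float32)
        mask = ndimage.binary_fill_holes(sl > body_threshold_hu)
        if mask.sum() < 4:
            continue
        cx = float((np.nonzero(mask)[0].mean() + 0.5) * sx)
        cy = float((np.nonzero(mask)[1].mean() + 0.5) * sy)
        n_theta = 256
        prof = _slice_radius_profile(mask, cx, cy, (sx, sy), n_theta)
        if a < 0 and float(prof.min()) + a < min_core_radius_mm:
            raise ValueError(
                "contraction would collapse the body below the airway-protect radius"
            )

        X, Y = np.meshgrid(gx - cx, gy - cy, indexing="ij")
        rho = np.hypot(X, Y)
        theta = np.mod(np.arctan2(Y, X), 2 * np.pi)
        ti = theta / (2 * np.pi) * n_theta
        R = np.interp(ti.ravel(), np.arange(n_theta + 1), np.append(prof, prof[0])).reshape(rho.shape)

        stretch = max(protect_margin_mm, -a + 3.0)
        rho_fix = np.maximum(R - stretch, 0.0)
        outer_new = np.maximum(R + a - rho_fix, 1e-3)
        outer_old = np.maximum(R - rho_fix, 1e-3)
        rho_src = np.where(
            rho <= rho_fix,
            rho,
            np.where(
                rho <= R + a,
                rho_fix + (rho - rho_fix) * outer_old / outer_new,
                rho - a,
            ),
        )
        xs = (cx + rho_src * np.where(rho > 0, X / np.maximum(rho, 1e-9), 0.0)) / sx - 0.5
        ys = (cy + rho_src * np.where(rho > 0, Y / np.maximum(rho, 1e-9), 0.0)) / sy - 0.5
        out[:, :, k] = ndimage.map_coordinates(
            sl, [xs, ys], order=1, mode="constant", cval=air_hu
        )

    return CtVolume(out, ct.spacing_mm, ct.origin_mm)
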