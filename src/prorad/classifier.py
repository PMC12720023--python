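"""RSM dataset assembly and the multi-label deviation classifier.

Range-shift maps are the classifier input: each sample is one simulated
impaired-vs-reference PR comparison of one phantom, labelled with the
deviation class that produced it.  Splits are assigned at phantom level
(nothing from a test phantom ever reaches training), images are channel
normalised with train-split statistics so the mm magnitude scale survives
preprocessing, minority classes are oversampled with label-preserving
augmentation (sub-pixel translation, mild noise — no flips, which would swap
the AP/IS sign semantics), and a compact convolutional network with a
28-unit sigmoid head is trained with binary cross-entropy, AdamW and early
stopping.  Evaluation reports micro-averaged precision/recall/F1/F2 at the
0.5 threshold plus per-class and micro-averaged ROC AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import deviations as dev
from .calibration import CalibrationCurve, TissueBands, default_curve, perturb_curve
from .phantom import CtVolume, NeckRegion
from .pr_sim import BeamConfig, simulate_pr
from .range_maps import compute_rsm, range_shift_batch

__all__ = [
    "DatasetConfig",
    "EvalReport",
    "RsmDataset",
    "RsmClassifier",
    "TrainConfig",
    "build_dataset",
    "class_aware_augment",
    "evaluate",
    "predict",
    "train_classifier",
    "znormalize",
]

SPLITS = ("train", "val", "test")

#: Structured deviation categories (NONREL excluded: it means "none present").
CATEGORY_ORDER = ("AP", "BONE", "CONT", "EXP", "FAT", "IS", "SOFT")


def category_matrix(class_order: tuple[str, ...]) -> np.ndarray:
    """Binary map (n_classes, 7): which categories each class contains."""
    m = np.zeros((len(class_order), len(CATEGORY_ORDER)), dtype=np.float32)
    for i, cid in enumerate(class_order):
        for member in cid.split(" & "):
            if member in CATEGORY_ORDER:
                m[i, CATEGORY_ORDER.index(member)] = 1.0
    return m


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize preserving the mm value scale."""
    if img.shape == shape:
        return img.astype(np.float32)
    rows = np.linspace(0, img.shape[0] - 1, shape[0])
    cols = np.linspace(0, img.shape[1] - 1, shape[1])
    R, C = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(img, [R, C], order=1, mode="nearest").astype(
        np.float32
    )


@dataclass
class RsmDataset:
    """A stack of RSM images with labels, phantom ids and split assignment."""

    images: np.ndarray  # (n, H, W) float32, mm
    labels: np.ndarray  # (n, 28) int8, canonical class order
    phantom_id: np.ndarray  # (n,) str
    split: np.ndarray  # (n,) in {"train","val","test"}
    class_order: tuple[str, ...] = field(
        default_factory=lambda: tuple(dev.enumerate_classes())
    )
    #: optional per-sample ground-truth magnitudes (n, 6):
    #: d_ap_mm, d_is_mm, deform_mm, 100*p_fat, 100*p_soft, 100*p_bone —
    #: used as auxiliary regression supervision during training only
    magnitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.images.shape[0]
        if not (self.labels.shape[0] == self.phantom_id.shape[0] == self.split.shape[0] == n):
            raise ValueError("inconsistent sample counts")
        if self.labels.shape[1] != len(self.class_order):
            raise ValueError("label matrix width does not match class order")
        self.assert_no_leakage()

    def assert_no_leakage(self) -> None:
        """Every phantom id must live in exactly one split."""
        seen: dict[str, str] = {}
        for pid, sp in zip(self.phantom_id, self.split):
            if pid in seen and seen[pid] != sp:
                raise ValueError(f"phantom {pid} appears in splits {seen[pid]} and {sp}")
            seen[pid] = sp

    def indices(self, split: str) -> np.ndarray:
        return np.nonzero(self.split == split)[0]

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.indices(split)
        return self.images[idx], self.labels[idx]

    def save_h5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("phantom_id", data=np.asarray(self.phantom_id, dtype="S16"))
            f.create_dataset("split", data=np.asarray(self.split, dtype="S8"))
            if self.magnitudes is not None:
                f.create_dataset("magnitudes", data=self.magnitudes.astype(np.float32))
            f.attrs["class_order"] = json.dumps(list(self.class_order))
            f.attrs["sign_convention"] = "positive = WET increased"

    @classmethod
    def load_h5(cls, path: str | Path) -> "RsmDataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                images=f["images"][:],
                labels=f["labels"][:],
                phantom_id=f["phantom_id"][:].astype("U16"),
                split=f["split"][:].astype("U8"),
                class_order=tuple(json.loads(f.attrs["class_order"])),
                magnitudes=f["magnitudes"][:] if "magnitudes" in f else None,
            )


@dataclass(frozen=True)
class DatasetConfig:
    """Everything the RSM dataset pipeline needs besides the cohort."""

    beam: BeamConfig = field(default_factory=BeamConfig.desk)
    sampling: dev.SamplingConfig = field(default_factory=dev.SamplingConfig)
    thresholds: dev.RelevanceThresholds = field(default_factory=dev.RelevanceThresholds)
    neck_region: NeckRegion | None = None
    curve: CalibrationCurve | None = None
    bands: TissueBands = field(default_factory=TissueBands)
    split_ratios: tuple[float, float, float] = (22.0, 3.0, 7.0)
    image_size: int = 64
    window_mm: float = 30.0


def split_phantoms(
    ids: list[str], ratios: tuple[float, float, float]
) -> dict[str, str]:
    """Deterministic phantom-level split with the given proportions."""
    n = len(ids)
    total = sum(ratios)
    n_val = max(1, int(round(n * ratios[1] / total))) if n >= 3 else 0
    n_test = max(1, int(round(n * ratios[2] / total))) if n >= 2 else 0
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("too few phantoms for a three-way split")
    order = sorted(ids)
    out = {}
    for i, pid in enumerate(order):
        out[pid] = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
    return out


def build_dataset(
    cohort: list[tuple[str, int, CtVolume]],
    draws_per_class: int,
    rng: np.random.Generator,
    cfg: DatasetConfig | None = None,
) -> RsmDataset:
    """Run the full simulation pipeline into a labelled RSM dataset.

    For each phantom the reference PR (original CT, unperturbed curve, no
    shift) is simulated once; each sample then draws a deviation for its
    class, applies it (deformed CT, perturbed curve, shifted field),
    simulates the impaired PR and computes the RSM.  Deformed CTs are cached
    per (phantom, amplitude) within a phantom's pass.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    cfg = cfg or DatasetConfig()
    curve = cfg.curve or default_curve()
    classes = dev.enumerate_classes()
    split_of = split_phantoms([pid for pid, _, _ in cohort], cfg.split_ratios)

    images, labels, pids, mags = [], [], [], []
    for pid, _, ct in cohort:
        region = cfg.neck_region or _default_region(ct)
        pr_ref = simulate_pr(ct, curve, cfg.beam)
        z = pr_ref.pristine().z
        ref_curves = pr_ref.mixed_idds().reshape(-1, z.size)
        deform_cache: dict[float, CtVolume] = {0.0: ct}
        for class_id in classes:
            for _ in range(int(draws_per_class)):
                spec = dev.sample_deviation(class_id, rng, cfg.sampling)
                key = round(float(spec.deform_mm), 3)
                if key not in deform_cache:
                    deform_cache[key] = dev.deform_anatomy(ct, key, region)
                ct_imp = deform_cache[key]
                curve_imp = perturb_curve(curve, spec.pert, cfg.bands)
                pr_imp = simulate_pr(
                    ct_imp, curve_imp, cfg.beam, shift=(spec.d_ap_mm, spec.d_is_mm)
                )
                imp_curves = pr_imp.mixed_idds().reshape(-1, z.size)
                s = range_shift_batch(
                    ref_curves, imp_curves, z, window_mm=cfg.window_mm
                ).reshape(pr_ref.shape)
                images.append(_resize(s, (cfg.image_size, cfg.image_size)))
                labels.append(dev.assign_labels(spec, cfg.thresholds).vector())
                pids.append(pid)
                mags.append(
                    [
                        spec.d_ap_mm,
                        spec.d_is_mm,
                        spec.deform_mm,
                        100.0 * spec.pert.p_fat,
                        100.0 * spec.pert.p_soft,
                        100.0 * spec.pert.p_bone,
                    ]
                )

    pids_arr = np.asarray(pids)
    return RsmDataset(
        images=np.stack(images),
        labels=np.stack(labels),
        phantom_id=pids_arr,
        split=np.asarray([split_of[p] for p in pids_arr]),
        magnitudes=np.asarray(mags, dtype=np.float32),
    )


def _default_region(ct: CtVolume) -> NeckRegion:
    ex, ey, _ = ct.extent_mm
    return NeckRegion(z0_mm=40.0, z1_mm=140.0, center_x_mm=ex / 2, center_y_mm=ey / 2)


def znormalize(image: np.ndarray) -> np.ndarray:
    """Per-image z-score normalisation; a near-constant image maps to zeros."""
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    std = float(image.std())
    if std < 1e-8:
        return np.zeros_like(image, dtype=np.float32)
    return ((image - image.mean()) / std).astype(np.float32)


def class_aware_augment(
    ds: RsmDataset,
    target_per_class: int,
    rng: np.random.Generator,
    max_shift_px: float = 2.0,
    noise_sigma_mm: float = 0.15,
) -> RsmDataset:
    """Oversample minority classes in the train split to ``target_per_class``.

    Augmented copies are label-preserving: sub-pixel translation up to
    ``max_shift_px`` and additive Gaussian noise up to ``noise_sigma_mm``.
    Flips are deliberately excluded (they would swap AP/IS sign semantics).
    Validation and test splits are never touched.
    """
    train_idx = ds.indices("train")
    new_imgs, new_labels, new_pids, new_mags = [], [], [], []
    for ci, class_id in enumerate(ds.class_order):
        members = train_idx[ds.labels[train_idx, ci] == 1]
        if members.size == 0:
            raise ValueError(f"class {class_id!r} has no training samples")
        deficit = int(target_per_class) - members.size
        for _ in range(max(0, deficit)):
            src = int(rng.choice(members))
            img = ds.images[src]
            shift = rng.uniform(-max_shift_px, max_shift_px, size=2)
            img = ndimage.shift(img, shift, order=1, mode="nearest")
            img = img + rng.normal(0.0, rng.uniform(0.0, noise_sigma_mm), img.shape)
            new_imgs.append(img.astype(np.float32))
            new_labels.append(ds.labels[src])
            new_pids.append(ds.phantom_id[src])
            if ds.magnitudes is not None:
                new_mags.append(ds.magnitudes[src])
    if not new_imgs:
        return ds
    return RsmDataset(
        images=np.concatenate([ds.images, np.stack(new_imgs)]),
        labels=np.concatenate([ds.labels, np.stack(new_labels)]),
        phantom_id=np.concatenate([ds.phantom_id, np.asarray(new_pids)]),
        split=np.concatenate([ds.split, np.full(len(new_imgs), "train")]),
        class_order=ds.class_order,
        magnitudes=None
        if ds.magnitudes is None
        else np.concatenate([ds.magnitudes, np.stack(new_mags)]),
    )


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe for the compact classifier."""

    architecture: str = "compact"
    lr: float = 3e-3
    weight_decay: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 130
    warmup_epochs: int = 3
    patience: int = 30
    lr_patience: int = 10
    lr_factor: float = 0.5
    pos_weight: float = 2.0
    aux_weight: float = 1.0
    magnitude_weight: float = 1.5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class RsmClassifier:
    """Compact CNN: 3 conv blocks, spatial flatten, hidden dense, 28-unit sigmoid head.

    Inputs are channel-normalised with dataset-level (train split) mean/std
    so the mm magnitude scale of the range shifts — the feature separating
    background-level from clinically relevant deviations — survives
    preprocessing.  The final feature map is flattened rather than
    globally pooled: the classes are defined by *where* in the field the
    range shifts sit (neck ring, AP/IS edge bands, spine column), so the
    head needs the coarse spatial layout.
    """

    def __init__(self, n_classes: int, cfg: TrainConfig, input_size: int):
        from . import nn

        if cfg.architecture != "compact":
            raise ValueError(f"unknown architecture preset {cfg.architecture!r}")
        if input_size % 8 != 0:
            raise ValueError("input size must be a multiple of 8")
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.input_size = input_size
        self.n_classes = n_classes
        self.norm_mean = 0.0
        self.norm_std = 1.0
        s = input_size // 8
        features = [
            nn.Conv2d(1, 16, rng),
            nn.BatchNorm2d(16),
            nn.ReLU(),
            nn.MaxPool2d(),
            nn.Conv2d(16, 32, rng),
            nn.BatchNorm2d(32),
            nn.ReLU(),
            nn.MaxPool2d(),
            nn.Conv2d(32, 64, rng),
            nn.BatchNorm2d(64),
            nn.ReLU(),
            nn.MaxPool2d(),
            nn.Flatten(),
            nn.Dense(64 * s * s, 256, rng),
            nn.ReLU(),
            nn.Dropout(0.15, np.random.default_rng(cfg.seed + 7)),
        ]
        # structured head: 7 category detectors composed into the 28
        # subset-classes; only the category detectors carry free parameters
        membership = category_matrix(tuple(dev.enumerate_classes()))
        self.net = nn.Sequential(
            features
            + [nn.Dense(256, len(CATEGORY_ORDER), rng), nn.ComposeClasses(membership)]
        )

    def set_normalization(self, mean: float, std: float) -> None:
        self.norm_mean = float(mean)
        self.norm_std = float(std) if std > 1e-8 else 1.0

    def _prep(self, images: np.ndarray) -> np.ndarray:
        if images.ndim == 2:
            images = images[None]
        x = (np.asarray(images, dtype=np.float32) - np.float32(self.norm_mean)) / np.float32(
            self.norm_std
        )
        return x[:, None, :, :]

    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._prep(images) if images.ndim != 4 else images, train)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        from . import nn

        out = []
        x = self._prep(images)
        for i in range(0, x.shape[0], 256):
            out.append(nn.sigmoid(self.net.forward(x[i : i + 256], train=False)))
        return np.concatenate(out)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", *self.net.get_weights())
        (path / "config.json").write_text(
            json.dumps(
                {
                    "train_config": asdict(self.cfg),
                    "input_size": self.input_size,
                    "n_classes": self.n_classes,
                    "normalization": [self.norm_mean, self.norm_std],
                    "class_order": dev.enumerate_classes(),
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "RsmClassifier":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        model = cls(
            meta["n_classes"], TrainConfig(**meta["train_config"]), meta["input_size"]
        )
        model.set_normalization(*meta.get("normalization", (0.0, 1.0)))
        with np.load(path / "weights.npz") as data:
            model.net.set_weights([data[k] for k in data.files])
        return model


def train_classifier(
    ds: RsmDataset, cfg: TrainConfig | None = None
) -> tuple[RsmClassifier, dict]:
    """Train on the train split with early stopping on validation loss.

    Returns the model restored to its best-validation-loss weights plus a
    history dict with per-epoch train/val loss and subset accuracy.
    """
    from . import nn

    cfg = cfg or TrainConfig()
    x_train, y_train = ds.subset("train")
    x_val, y_val = ds.subset("val")
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("train and val splits must be non-empty")

    model = RsmClassifier(ds.labels.shape[1], cfg, ds.images.shape[1])
    model.set_normalization(float(x_train.mean()), float(x_train.std()))
    xt = model._prep(x_train)
    xv = model._prep(x_val)
    yt = y_train.astype(np.float32)
    yv = y_val.astype(np.float32)

    # auxiliary category targets: which of the 7 categories each sample holds
    cat_map = category_matrix(ds.class_order)
    yt_cat = yt @ cat_map

    # auxiliary magnitude-regression targets (scaled to unit-ish range):
    # forcing the trunk to estimate deviation amplitudes sharpens the
    # decision boundary between background-level and relevant deviations
    mag_head = None
    yt_mag = None
    if cfg.magnitude_weight > 0 and ds.magnitudes is not None:
        scale = np.asarray([4.0, 4.0, 12.0, 5.0, 5.0, 11.0], dtype=np.float32)
        yt_mag = (ds.magnitudes[ds.indices("train")] / scale).astype(np.float32)
        mag_head = nn.Dense(256, yt_mag.shape[1], np.random.default_rng(cfg.seed + 3))

    params = model.net.params + (mag_head.params if mag_head else [])
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    history = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}

    best_loss, best_weights, best_epoch, bad = np.inf, model.net.get_weights(), 0, 0
    features = model.net.layers[:-2]  # up to the 256-dim representation
    cat_dense = model.net.layers[-2]  # 256 -> 7 category logits
    head = model.net.layers[-1]  # subset composition

    def _eval(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        # monitoring loss is plain BCE: smoother than the pos-weighted
        # training objective, which matters for early-stop robustness
        losses, correct, total = [], 0, 0
        for i in range(0, x.shape[0], 256):
            logits = model.net.forward(x[i : i + 256], train=False)
            loss, _ = nn.bce_with_logits(logits, y[i : i + 256])
            losses.append(loss * (logits.shape[0]))
            pred = nn.sigmoid(logits) > cfg.threshold
            correct += int(np.all(pred == (y[i : i + 256] > 0.5), axis=1).sum())
            total += logits.shape[0]
        return float(np.sum(losses) / total), correct / total

    base_lr = cfg.lr
    for epoch in range(cfg.max_epochs):
        if cfg.warmup_epochs and epoch < cfg.warmup_epochs:
            # linear warmup stabilises the structured head across inits
            opt.lr = base_lr * (epoch + 1) / (cfg.warmup_epochs + 1)
        elif epoch == cfg.warmup_epochs:
            opt.lr = base_lr
        order = rng.permutation(xt.shape[0])
        for i in range(0, order.size, cfg.batch_size):
            b = order[i : i + cfg.batch_size]
            h = xt[b]
            for layer in features:
                h = layer.forward(h, True)
            z = cat_dense.forward(h, True)
            logits = head.forward(z, True)
            loss, grad = nn.bce_with_logits(logits, yt[b], cfg.pos_weight)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            gz = head.backward(grad)
            if cfg.aux_weight > 0:
                # direct supervision of the category logits
                _, grad_a = nn.bce_with_logits(z, yt_cat[b], cfg.pos_weight)
                gz = gz + np.float32(cfg.aux_weight) * grad_a
            gh = cat_dense.backward(gz)
            if mag_head is not None:
                m = mag_head.forward(h, True)
                dm = m - yt_mag[b]
                gh = gh + mag_head.backward(
                    np.float32(2.0 * cfg.magnitude_weight) * dm / dm.size
                )
            for layer in reversed(features):
                gh = layer.backward(gh)
            opt.step(model.net.grads + (mag_head.grads if mag_head else []))
        # history train metrics on a fixed subsample (keeps epochs cheap)
        n_hist = min(768, xt.shape[0])
        tl, ta = _eval(xt[:n_hist], yt[:n_hist])
        vl, va = _eval(xv, yv)
        history["train_loss"].append(tl)
        history["val_loss"].append(vl)
        history["train_acc"].append(ta)
        history["val_acc"].append(va)
        if vl < best_loss - 1e-6:
            best_loss, best_weights, best_epoch, bad = vl, model.net.get_weights(), epoch, 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
            if bad % cfg.lr_patience == 0:  # reduce on plateau
                opt.lr *= cfg.lr_factor

    model.net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return model, history


def predict(
    model: RsmClassifier, image: np.ndarray, threshold: float | None = None
) -> tuple[np.ndarray, dev.LabelSet | None]:
    """Probabilities and thresholded labels for one RSM image.

    Returns ``(probs, label_set)``; ``label_set`` is ``None`` when no class
    exceeds the threshold (abstention — distinct from predicting NONREL).
    """
    thr = model.cfg.threshold if threshold is None else threshold
    probs = model.predict_proba(image[None] if image.ndim == 2 else image)[0]
    order = dev.enumerate_classes()
    pos = [order[i] for i in np.nonzero(probs > thr)[0]]
    if not pos:
        return probs, None
    if "NONREL" in pos and len(pos) > 1:
        pos = ["NONREL"] if probs[order.index("NONREL")] == max(
            probs[order.index(c)] for c in pos
        ) else [c for c in pos if c != "NONREL"]
    try:
        labels = dev.LabelSet(tuple(pos))
    except ValueError:
        # predicted set falls outside the taxonomy; report raw top class
        labels = dev.LabelSet((order[int(np.argmax(probs))],))
    return probs, labels


@dataclass(frozen=True)
class EvalReport:
    """Micro-averaged multi-label metrics plus ROC summaries."""

    precision: float
    recall: float
    f1: float
    f2: float
    micro_auc: float
    per_class_auc: dict[str, float | None]
    macro_auc: float
    n_samples: int
    undefined_auc_classes: tuple[str, ...]
    confusion: dict[str, int]
    inference_ms_per_image: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _roc_auc(y: np.ndarray, p: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, p))


def evaluate(
    model: RsmClassifier, ds: RsmDataset, split: str = "test"
) -> EvalReport:
    """Micro P/R/F1/F2 at the decision threshold and ROC AUCs on a split."""
    import time

    ds.assert_no_leakage()
    x, y = ds.subset(split)
    if x.shape[0] == 0:
        raise ValueError(f"split {split!r} is empty")
    t0 = time.perf_counter()
    probs = model.predict_proba(x)
    ms_per_image = 1000.0 * (time.perf_counter() - t0) / x.shape[0]
    pred = probs > model.cfg.threshold

    yb = y > 0.5
    tp = int(np.sum(pred & yb))
    fp = int(np.sum(pred & ~yb))
    fn = int(np.sum(~pred & yb))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    f2 = 5 * precision * recall / (4 * precision + recall) if precision + recall else 0.0

    per_class: dict[str, float | None] = {}
    undefined = []
    for ci, cname in enumerate(ds.class_order):
        col = yb[:, ci]
        if col.all() or not col.any():
            per_class[cname] = None
            undefined.append(cname)
        else:
            per_class[cname] = _roc_auc(col, probs[:, ci])
    defined = [v for v in per_class.values() if v is not None]
    micro_auc = _roc_auc(yb.ravel(), probs.ravel())

    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        f2=f2,
        micro_auc=micro_auc,
        per_class_auc=per_class,
        macro_auc=float(np.mean(defined)) if defined else float("nan"),
        n_samples=int(x.shape[0]),
        undefined_auc_classes=tuple(undefined),
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": int(np.sum(~pred & ~yb))},
        inference_ms_per_image=ms_per_image,
    )
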