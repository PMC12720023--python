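"""End-to-end workflow orchestration: cohort -> PR -> RSM dataset -> CNN.

A run is fully described by a :class:`RunConfig`; every artifact carries the
config hash that produced it, and a manifest records seeds, stage timings
and the package version so a run is reconstructable from the manifest alone.
The master seed fans out into independent streams for phantom generation,
deviation sampling, augmentation and weight initialisation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import deviations as dev
from .classifier import (
    DatasetConfig,
    EvalReport,
    RsmDataset,
    TrainConfig,
    build_dataset,
    class_aware_augment,
    evaluate,
    train_classifier,
)
from .phantom import PhantomSpec, generate_cohort, neck_region
from .pr_sim import BeamConfig, pristine_idd, simulate_pr
from .range_maps import RreMap, rpqc_grid, rre_map

__all__ = ["RunConfig", "run_pipeline", "validate_physics", "desk_config", "clinical_config"]


@dataclass(frozen=True)
class RunConfig:
    """Fully explicit configuration of an end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    beam: BeamConfig = field(default_factory=BeamConfig.desk)
    sampling: dev.SamplingConfig = field(default_factory=dev.SamplingConfig)
    thresholds: dev.RelevanceThresholds = field(default_factory=dev.RelevanceThresholds)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_phantoms: int = 8
    draws_per_class: int = 12
    augment_target_per_class: int = 100
    image_size: int = 32  # native desk RSM grid is 33x33
    master_seed: int = 7
    scale_preset: str = "desk"

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.master_seed % 2**31)
        kids = ss.spawn(4)
        names = ["phantom", "deviation", "augment", "weights"]
        return {n: int(k.generate_state(1)[0] % 2**31) for n, k in zip(names, kids)}


def desk_config(master_seed: int = 7, **overrides) -> RunConfig:
    """Desk-scale preset: 8 phantoms, 128 mm / 4 mm field, 32x32 classifier input."""
    return RunConfig(master_seed=master_seed, **overrides)


def clinical_config(master_seed: int = 7) -> RunConfig:
    """Clinical-scale preset: 260x260 mm field at 1 mm spacing, 1 mm CT.

    Expensive; guarded behind ``allow_large`` in :func:`run_pipeline`.
    """
    return RunConfig(
        phantom=PhantomSpec(voxel_spacing_mm=(1.0, 1.0, 1.0), grid_shape=(256, 256, 320)),
        beam=BeamConfig(),
        n_phantoms=32,
        draws_per_class=18,
        augment_target_per_class=450,
        image_size=64,
        master_seed=master_seed,
        scale_preset="clinical",
    )


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    allow_large: bool = False,
    save_dataset: bool = True,
) -> dict:
    """Execute cohort -> dataset -> train -> evaluate; write all artifacts.

    Returns the manifest dict.  Stages that already produced an artifact
    with the current config hash are resumed from disk.
    """
    if config.scale_preset == "clinical" and not allow_large:
        raise RuntimeError(
            "the clinical-scale preset is hours of compute; pass allow_large=True to proceed"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds()
    chash = config.config_hash()
    timings: dict[str, float] = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *a):
                timings[name] = round(time.perf_counter() - self.t0, 2)

        return _T()

    ds_path = out / "dataset.h5"
    if ds_path.exists() and _artifact_hash(out, "dataset") == chash:
        ds = RsmDataset.load_h5(ds_path)
        timings["dataset"] = 0.0
    else:
        with _stage("cohort"):
            cohort = generate_cohort(config.n_phantoms, config.phantom, seeds["phantom"])
        with _stage("dataset"):
            ds_cfg = DatasetConfig(
                beam=config.beam,
                sampling=config.sampling,
                thresholds=config.thresholds,
                neck_region=neck_region(config.phantom),
                image_size=config.image_size,
            )
            rng = np.random.default_rng(seeds["deviation"])
            ds = build_dataset(cohort, config.draws_per_class, rng, ds_cfg)
        if save_dataset:
            ds.save_h5(ds_path)
            _record_hash(out, "dataset", chash)

    with _stage("augment"):
        ds_aug = class_aware_augment(
            ds, config.augment_target_per_class, np.random.default_rng(seeds["augment"])
        )

    with _stage("train"):
        train_cfg = dataclasses.replace(config.train, seed=seeds["weights"])
        model, history = train_classifier(ds_aug, train_cfg)
    model.save(out / "model")
    (out / "history.json").write_text(json.dumps(history))

    with _stage("evaluate"):
        report = evaluate(model, ds_aug, "test")
    report.to_json(out / "report.json")

    manifest = {
        "tool": "prorad",
        "version": __version__,
        "config": asdict(config),
        "config_hash": chash,
        "seeds": seeds,
        "timings_s": timings,
        "n_samples": int(ds.images.shape[0]),
        "n_samples_augmented": int(ds_aug.images.shape[0]),
        "report": {
            "precision": report.precision,
            "recall": report.recall,
            "f1": report.f1,
            "f2": report.f2,
            "micro_auc": report.micro_auc,
            "min_per_class_auc": min(
                v for v in report.per_class_auc.values() if v is not None
            ),
            "n_test": report.n_samples,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _record_hash(out: Path, stage: str, chash: str) -> None:
    p = out / "hashes.json"
    data = json.loads(p.read_text()) if p.exists() else {}
    data[stage] = chash
    p.write_text(json.dumps(data))


def _artifact_hash(out: Path, stage: str) -> str | None:
    p = out / "hashes.json"
    if not p.exists():
        return None
    return json.loads(p.read_text()).get(stage)


def validate_physics(
    config: RunConfig,
    noise_fraction_of_peak: float = 0.01,
    seed: int | None = None,
) -> list[dict]:
    """RP-QC style check on each test-split phantom.

    Simulates the sparse 81-spot QC field through each phantom, builds a
    pseudo-measurement by adding iid depth noise (default 1% of the peak) to
    the simulated IDDs, and summarises the relative range error as mean
    +/- 1.5 SD against the +/-3% clinical margin.
    """
    from .classifier import split_phantoms

    seeds = config.seeds()
    rng = np.random.default_rng(seeds["deviation"] if seed is None else seed)
    cohort = generate_cohort(config.n_phantoms, config.phantom, seeds["phantom"])
    split_of = split_phantoms([pid for pid, _, _ in cohort], (22.0, 3.0, 7.0))

    spots = rpqc_grid((40.0, 40.0), 5.0)
    reports = []
    for pid, _, ct in cohort:
        if split_of[pid] != "test":
            continue
        cfg_qc = dataclasses.replace(
            config.beam, field_size_mm=(40.0, 40.0), spot_spacing_mm=5.0
        )
        pr = simulate_pr(ct, _curve(), cfg_qc)
        z = pr.pristine().z
        sim = pr.mixed_idds().reshape(-1, z.size)
        if sim.shape[0] != spots.shape[0]:
            raise RuntimeError("QC spot grid mismatch")
        peak = sim.max()
        meas = np.maximum(sim + rng.normal(0.0, noise_fraction_of_peak * peak, sim.shape), 0.0)
        rm: RreMap = rre_map(sim, meas, config.beam.water_range_r0_mm, z=z)
        reports.append(
            {
                "phantom_id": pid,
                "mean_rre_percent": rm.mean,
                "band_1p5_sd_percent": rm.k_sd,
                "passed": bool(rm.passed),
                "n_spots": int(sim.shape[0]),
            }
        )
    return reports


def _curve():
    from .calibration import default_curve

    return default_curve()
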