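"""Dataset assembly, normalisation, augmentation, training, and metrics."""

import dataclasses
import types

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prorad import deviations as dev
from prorad.classifier import (
    DatasetConfig,
    RsmClassifier,
    RsmDataset,
    TrainConfig,
    build_dataset,
    class_aware_augment,
    evaluate,
    predict,
    split_phantoms,
    train_classifier,
    znormalize,
)
from prorad.phantom import PhantomSpec, generate_cohort, neck_region
from prorad.pr_sim import BeamConfig


def _toy_dataset(
    n_per_class: int = 6,
    n_classes: int = 28,
    size: int = 16,
    seed: int = 0,
    n_phantoms: int = 6,
) -> RsmDataset:
    """Synthetic stand-in dataset: each class is a distinct spatial pattern."""
    n_phantoms = min(n_phantoms, n_per_class)  # every phantom must have samples
    rng = np.random.default_rng(seed)
    imgs, labels, pids = [], [], []
    split_of = split_phantoms([f"p{i:03d}" for i in range(n_phantoms)], (4.0, 1.0, 1.0))
    for ci in range(n_classes):
        base = np.zeros((size, size), dtype=np.float32)
        base[(ci * 3) % size, :] = 5.0
        base[:, (ci * 7) % size] = -4.0
        for k in range(n_per_class):
            img = base + rng.normal(0, 0.3, base.shape).astype(np.float32)
            row = np.zeros(n_classes, dtype=np.int8)
            row[ci] = 1
            imgs.append(img)
            labels.append(row)
            pids.append(f"p{k % n_phantoms:03d}")
    pids = np.asarray(pids)
    return RsmDataset(
        images=np.stack(imgs),
        labels=np.stack(labels),
        phantom_id=pids,
        split=np.asarray([split_of[p] for p in pids]),
    )


class TestZnormalize:
    def test_constant_image_guard(self):
        out = znormalize(np.full((8, 8), 3.7))
        np.testing.assert_array_equal(out, 0.0)

    def test_mean_zero_std_one(self):
        rng = np.random.default_rng(0)
        out = znormalize(rng.normal(2.0, 5.0, (16, 16)))
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (12, 12))
        np.testing.assert_allclose(znormalize(a * x + b), znormalize(x), atol=1e-4)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            znormalize(np.array([[np.nan, 1.0]]))


class TestSplitsAndLeakage:
    def test_split_ratios(self):
        ids = [f"p{i:03d}" for i in range(10)]
        split = split_phantoms(ids, (0.7, 0.1, 0.2))
        counts = {s: sum(v == s for v in split.values()) for s in ("train", "val", "test")}
        assert counts == {"train": 7, "val": 1, "test": 2}

    def test_desk_proportions(self):
        split = split_phantoms([f"p{i:03d}" for i in range(8)], (22.0, 3.0, 7.0))
        counts = {s: sum(v == s for v in split.values()) for s in ("train", "val", "test")}
        assert counts == {"train": 5, "val": 1, "test": 2}

    def test_leakage_detected(self):
        ds = _toy_dataset()
        split = ds.split.copy()
        # force one phantom into two splits
        i = np.nonzero(ds.phantom_id == "p000")[0]
        split[i[0]] = "train"
        split[i[1]] = "test"
        with pytest.raises(ValueError, match="appears in splits"):
            RsmDataset(ds.images, ds.labels, ds.phantom_id, split)


class TestAugmentation:
    def test_balanced_input_unchanged(self):
        ds = _toy_dataset()
        n_train = (ds.split == "train").sum()
        per_class = n_train // 28
        out = class_aware_augment(ds, per_class, np.random.default_rng(0))
        assert out.images.shape[0] == ds.images.shape[0]

    def test_oversamples_to_target_with_identical_labels(self):
        ds = _toy_dataset(n_per_class=6)
        out = class_aware_augment(ds, 20, np.random.default_rng(0))
        tr = out.indices("train")
        for ci in range(28):
            assert out.labels[tr, ci].sum() >= 20

    def test_val_test_untouched(self):
        ds = _toy_dataset()
        out = class_aware_augment(ds, 50, np.random.default_rng(0))
        for split in ("val", "test"):
            assert (out.split == split).sum() == (ds.split == split).sum()

    def test_missing_class_reported(self):
        ds = _toy_dataset()
        keep = ds.labels[:, 0] == 0  # drop the first class entirely
        ds2 = RsmDataset(
            ds.images[keep], ds.labels[keep], ds.phantom_id[keep], ds.split[keep]
        )
        with pytest.raises(ValueError, match="AP"):
            class_aware_augment(ds2, 10, np.random.default_rng(0))


class TestTraining:
    def test_overfits_small_sample(self):
        """Capacity check: the compact net drives train loss below 0.05."""
        ds = _toy_dataset(n_per_class=4, size=16)
        cfg = TrainConfig(max_epochs=200, patience=200, lr=3e-3, seed=0)
        model, hist = train_classifier(ds, cfg)
        assert min(hist["train_loss"]) < 0.05

    def test_seeded_determinism(self):
        ds = _toy_dataset(n_per_class=4, size=16)
        cfg = TrainConfig(max_epochs=4, patience=10, seed=3)
        _, h1 = train_classifier(ds, cfg)
        _, h2 = train_classifier(ds, cfg)
        assert h1["val_loss"] == h2["val_loss"]

    def test_early_stop_restores_best_val_loss(self):
        ds = _toy_dataset(n_per_class=4, size=16)
        cfg = TrainConfig(max_epochs=30, patience=5, seed=1)
        model, hist = train_classifier(ds, cfg)
        best = hist["best_epoch"]
        assert hist["val_loss"][best] == min(hist["val_loss"])
        assert all(hist["val_loss"][best] <= v for v in hist["val_loss"][best + 1 :])

    def test_learning_sanity(self):
        """Validation loss at the best epoch beats the first epoch."""
        ds = _toy_dataset(n_per_class=5, size=16)
        model, hist = train_classifier(ds, TrainConfig(max_epochs=15, patience=15, seed=2))
        assert hist["val_loss"][hist["best_epoch"]] < hist["val_loss"][0]

    def test_save_load_round_trip(self, tmp_path):
        ds = _toy_dataset(n_per_class=4, size=16)
        model, _ = train_classifier(ds, TrainConfig(max_epochs=3, patience=5, seed=0))
        model.save(tmp_path / "model")
        back = RsmClassifier.load(tmp_path / "model")
        x = ds.images[:5]
        np.testing.assert_allclose(back.predict_proba(x), model.predict_proba(x), atol=1e-6)


class TestPredict:
    def _model(self, probs):
        model = types.SimpleNamespace()
        model.cfg = TrainConfig()
        model.predict_proba = lambda x: np.asarray([probs])
        return model

    def test_abstention_when_nothing_confident(self):
        probs = np.full(28, 0.1)
        p, labels = predict(self._model(probs), np.zeros((8, 8)))
        assert labels is None

    def test_nonrel_prediction(self):
        order = dev.enumerate_classes()
        probs = np.full(28, 0.1)
        probs[order.index("NONREL")] = 0.9
        _, labels = predict(self._model(probs), np.zeros((8, 8)))
        assert labels.classes == ("NONREL",)

    def test_single_confident_class(self):
        order = dev.enumerate_classes()
        probs = np.full(28, 0.2)
        probs[order.index("BONE & IS")] = 0.8
        _, labels = predict(self._model(probs), np.zeros((8, 8)))
        assert labels.classes == ("BONE & IS",)


class TestEvaluate:
    def _stub_model(self, probs_fn):
        model = types.SimpleNamespace()
        model.cfg = TrainConfig()
        model.predict_proba = probs_fn
        return model

    def test_perfect_predictor(self):
        ds = _toy_dataset(n_per_class=4)
        model = self._stub_model(
            lambda x: ds.labels[ds.indices("test")].astype(float) * 0.98 + 0.01
        )
        rep = evaluate(model, ds, "test")
        assert rep.precision == rep.recall == rep.f1 == 1.0
        assert rep.micro_auc == 1.0

    def test_f2_formula(self):
        # P=0.5, R=1.0 -> F2 = 5PR/(4P+R) = 2.5/3
        p, r = 0.5, 1.0
        assert 5 * p * r / (4 * p + r) == pytest.approx(0.833333333)

    def test_metric_identities(self):
        """Reported F1/F2 must equal recomputation from reported P and R."""
        ds = _toy_dataset(n_per_class=4)
        rng = np.random.default_rng(5)
        noisy = ds.labels[ds.indices("test")].astype(float)
        flip = rng.random(noisy.shape) < 0.1
        model = self._stub_model(
            lambda x: np.clip(np.abs(noisy - flip * 1.0) * 0.9 + 0.05, 0, 1)
        )
        rep = evaluate(model, ds, "test")
        P, R = rep.precision, rep.recall
        assert rep.f1 == pytest.approx(2 * P * R / (P + R), abs=1e-12)
        assert rep.f2 == pytest.approx(5 * P * R / (4 * P + R), abs=1e-12)

    def test_micro_precision_matches_hand_count(self):
        """10% label flips: micro precision equals a direct confusion count."""
        ds = _toy_dataset(n_per_class=4)
        y = ds.labels[ds.indices("test")].astype(bool)
        rng = np.random.default_rng(7)
        flip = rng.random(y.shape) < 0.1
        pred = y ^ flip
        model = self._stub_model(lambda x: pred * 0.9 + 0.05)
        rep = evaluate(model, ds, "test")
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        assert rep.precision == pytest.approx(tp / (tp + fp))

    def test_roc_invariant_under_monotone_transform(self):
        ds = _toy_dataset(n_per_class=4)
        rng = np.random.default_rng(9)
        base = np.clip(
            ds.labels[ds.indices("test")].astype(float) * 0.6
            + rng.uniform(0, 0.4, (len(ds.indices("test")), 28)),
            0,
            1,
        )
        rep1 = evaluate(self._stub_model(lambda x: base), ds, "test")
        rep2 = evaluate(self._stub_model(lambda x: base**3), ds, "test")
        assert rep1.micro_auc == pytest.approx(rep2.micro_auc, abs=1e-12)

    def test_absent_class_auc_undefined(self):
        ds = _toy_dataset(n_per_class=4)
        y = ds.labels.copy()
        # remove a class from the test split only
        test_idx = ds.indices("test")
        ci = 2
        drop = test_idx[y[test_idx, ci] == 1]
        keep = np.setdiff1d(np.arange(len(y)), drop)
        ds2 = RsmDataset(ds.images[keep], y[keep], ds.phantom_id[keep], ds.split[keep])
        model = self._stub_model(
            lambda x: ds2.labels[ds2.indices("test")].astype(float) * 0.9 + 0.05
        )
        rep = evaluate(model, ds2, "test")
        assert ds2.class_order[ci] in rep.undefined_auc_classes
        assert rep.per_class_auc[ds2.class_order[ci]] is None


@pytest.fixture(scope="module")
def mini():
    spec = PhantomSpec()
    cohort = generate_cohort(2, spec, seed=21)
    cfg = DatasetConfig(
        beam=BeamConfig.desk(),
        neck_region=neck_region(spec),
        image_size=32,
        split_ratios=(1.0, 1.0, 0.0),
    )
    rng = np.random.default_rng(4)
    return build_dataset(cohort, 1, rng, cfg)


class TestBuildDataset:
    def test_sample_count_and_one_hot(self, mini):
        assert mini.images.shape[0] == 2 * 28
        np.testing.assert_array_equal(mini.labels.sum(axis=1), 1)

    def test_magnitudes_recorded(self, mini):
        assert mini.magnitudes.shape == (56, 6)
        order = dev.enumerate_classes()
        ap_rows = mini.labels[:, order.index("AP")] == 1
        assert np.all(np.abs(mini.magnitudes[ap_rows, 0]) >= 2.0)

    def test_images_match_compute_rsm(self, mini):
        """The pipeline's fast path equals the public compute_rsm route."""
        from prorad.calibration import default_curve
        from prorad.pr_sim import simulate_pr
        from prorad.range_maps import compute_rsm
        from prorad.classifier import _resize

        spec = PhantomSpec()
        cohort = generate_cohort(2, spec, seed=21)
        cfg = DatasetConfig(
            beam=BeamConfig.desk(),
            neck_region=neck_region(spec),
            image_size=32,
            split_ratios=(1.0, 1.0, 0.0),
        )
        # regenerate the first sample with the same rng stream
        rng = np.random.default_rng(4)
        first_class = dev.enumerate_classes()[0]
        spec_dev = dev.sample_deviation(first_class, rng, cfg.sampling)
        curve = default_curve()
        from prorad.calibration import perturb_curve

        pid, _, ct = cohort[0]
        pr_ref = simulate_pr(ct, curve, cfg.beam)
        pr_imp = simulate_pr(
            ct,
            perturb_curve(curve, spec_dev.pert, cfg.bands),
            cfg.beam,
            shift=(spec_dev.d_ap_mm, spec_dev.d_is_mm),
        )
        rsm = compute_rsm(pr_ref, pr_imp)
        expected = _resize(rsm.s_mm, (32, 32))
        np.testing.assert_allclose(mini.images[0], expected, atol=0.05)

    def test_dataset_h5_round_trip(self, mini, tmp_path):
        mini.save_h5(tmp_path / "ds.h5")
        back = RsmDataset.load_h5(tmp_path / "ds.h5")
        np.testing.assert_array_equal(back.images, mini.images)
        np.testing.assert_array_equal(back.labels, mini.labels)
        np.testing.assert_array_equal(back.magnitudes, mini.magnitudes)
        assert back.class_order == mini.class_order
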