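"""Classifier: architecture arithmetic, stratified folds, CV training."""

import numpy as np
import pytest

from msidl import BinningScheme, CoreAnnotation, MSIDataset
from msidl.classify import (ArchConfig, PredictionSet, TrainConfig, build_model,
                            load_model, load_predictions, per_class_accuracy,
                            save_model, save_predictions, stratified_folds,
                            train_cv)
from msidl.nn import Dense

from conftest import make_flat_dataset

TINY_ARCH = ArchConfig(n_conv_blocks=2, channels=(4, 8), kernel_size=5,
                       pool_size=4, n_classes=3)


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        ds = make_flat_dataset({c: 100 for c in "ABCDEFGH"})
        fa = stratified_folds(ds, k=5, seed=0)
        labels = ds.labels
        for cls in "ABCDEFGH":
            counts = np.bincount(fa.folds[labels == cls], minlength=5)
            assert np.all(counts == 20)

    def test_remainder_handling(self):
        ds = make_flat_dataset({"A": 101, "B": 100})
        fa = stratified_folds(ds, k=5, seed=0)
        counts = np.bincount(fa.folds[ds.labels == "A"], minlength=5)
        assert set(counts) <= {20, 21} and counts.sum() == 101

    def test_determinism(self):
        ds = make_flat_dataset({"A": 30, "B": 30})
        f1 = stratified_folds(ds, k=5, seed=3).folds
        f2 = stratified_folds(ds, k=5, seed=3).folds
        assert np.array_equal(f1, f2)
        f3 = stratified_folds(ds, k=5, seed=4).folds
        assert not np.array_equal(f1, f3)

    def test_small_class_rejected_with_name(self):
        ds = make_flat_dataset({"A": 30, "Tiny": 3})
        with pytest.raises(ValueError, match="Tiny"):
            stratified_folds(ds, k=5)

    def test_core_level_split_keeps_cores_whole(self):
        ds = make_flat_dataset({f"C{i}": 4 for i in range(12)})
        # regroup the 12 cores into 2 classes of 6 cores
        for a in ds.annotations:
            a.label = "X" if int(a.core_id[1:].split("_")[0]) < 6 else "Y"
        ds.class_order = ["X", "Y"]
        fa = stratified_folds(ds, k=3, seed=0, split_by="core")
        for cid in set(ds.core_ids):
            assert len(set(fa.folds[ds.core_ids == cid])) == 1


class TestBuildModel:
    def test_flatten_length_arithmetic(self):
        arch = ArchConfig(n_conv_blocks=6, channels=(8, 16, 32, 64, 128, 128),
                          kernel_size=9, pool_size=4, n_classes=8)
        model = build_model(arch, 4096, seed=0)
        dense = [l for l in model.net.layers if isinstance(l, Dense)][0]
        assert dense.W.shape == (8, 128 * 1)        # 4096 / 4**6 == 1

    def test_forward_on_zero_spectrum_is_finite(self):
        model = build_model(TINY_ARCH, 64, seed=0)
        scores = model.forward(np.zeros(64))
        assert scores.shape == (1, 3) and np.all(np.isfinite(scores))

    def test_same_seed_identical_weights(self):
        m1 = build_model(TINY_ARCH, 64, seed=5)
        m2 = build_model(TINY_ARCH, 64, seed=5)
        for p1, p2 in zip(m1.net.params(), m2.net.params()):
            assert np.array_equal(p1, p2)

    def test_pool_collapse_names_block(self):
        arch = ArchConfig(n_conv_blocks=3, channels=(2, 2, 2), kernel_size=3,
                          pool_size=4, n_classes=2)
        with pytest.raises(ValueError, match="block 2"):
            build_model(arch, 32, seed=0)


def _separable_dataset(n_per_class=30, n_bins=64, seed=0):
    """Three classes, each with one characteristic hot bin plus mild noise."""
    rng = np.random.default_rng(seed)
    ds = make_flat_dataset({"a": n_per_class, "b": n_per_class, "c": n_per_class},
                           n_bins=n_bins, seed=seed)
    ds.intensities[:] = rng.random(ds.intensities.shape).astype(np.float32) * 0.05
    hot = {"a": 10, "b": 30, "c": 50}
    for i, lab in enumerate(ds.labels):
        ds.intensities[i, hot[lab]] = 1.0
    return ds


class TestTrainCV:
    def test_separable_dataset_reaches_100_percent(self):
        ds = _separable_dataset()
        cfg = TrainConfig(epochs=30, batch_size=16, seed=1, k_folds=5)
        models, preds = train_cv(ds, TINY_ARCH, cfg)
        assert len(models) == 5
        assert preds.overall_accuracy() == 100.0
        acc = per_class_accuracy(preds)
        assert all(v == 100.0 for v in acc.values())

    def test_every_pixel_predicted_exactly_once(self):
        ds = _separable_dataset(n_per_class=10)
        cfg = TrainConfig(epochs=2, batch_size=16, seed=1, k_folds=5)
        _, preds = train_cv(ds, TINY_ARCH, cfg)
        assert len(preds) == ds.n_pixels
        # each record corresponds to a unique pixel coordinate
        assert len({tuple(c) for c in preds.coords}) == ds.n_pixels

    def test_reproducible_with_fixed_seed(self):
        ds = _separable_dataset(n_per_class=10)
        cfg = TrainConfig(epochs=2, batch_size=16, seed=9, k_folds=2)
        _, p1 = train_cv(ds, TINY_ARCH, cfg)
        _, p2 = train_cv(ds, TINY_ARCH, cfg)
        assert np.array_equal(p1.scores, p2.scores)
        assert (p1.pred_labels == p2.pred_labels).all()

    def test_beats_majority_class_predictor(self):
        ds = _separable_dataset(n_per_class=20)
        cfg = TrainConfig(epochs=10, batch_size=16, seed=2, k_folds=3)
        _, preds = train_cv(ds, TINY_ARCH, cfg)
        counts = np.bincount([ds.class_order.index(l) for l in ds.labels])
        majority = 100.0 * counts.max() / counts.sum()
        assert preds.overall_accuracy() >= majority


def _hand_preds(true, pred, fold, classes):
    n = len(true)
    return PredictionSet(
        true_labels=np.array(true, dtype=object),
        pred_labels=np.array(pred, dtype=object),
        scores=np.zeros((n, len(classes))),
        fold=np.asarray(fold),
        core_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        coords=np.column_stack([np.arange(n), np.zeros(n, dtype=int)]),
        class_order=classes,
    )


class TestPerClassAccuracy:
    def test_all_correct(self):
        p = _hand_preds(["a", "b"] * 4, ["a", "b"] * 4, [0, 0, 0, 0, 1, 1, 1, 1],
                        ["a", "b"])
        assert per_class_accuracy(p) == {"a": 100.0, "b": 100.0}

    def test_three_of_four_in_one_fold(self):
        p = _hand_preds(["a"] * 4, ["a", "a", "a", "b"], [0] * 4, ["a", "b"])
        assert per_class_accuracy(p)["a"] == 75.0

    def test_fold_averaging_weights_folds_equally(self):
        # fold 0: 1/2 correct; fold 1: 4/4 correct -> mean of 50 and 100
        p = _hand_preds(["a"] * 6, ["a", "b", "a", "a", "a", "a"],
                        [0, 0, 1, 1, 1, 1], ["a", "b"])
        assert per_class_accuracy(p)["a"] == 75.0

    def test_record_order_invariance(self):
        rng = np.random.default_rng(0)
        true = ["a", "b", "a", "b", "a", "b"]
        pred = ["a", "b", "b", "b", "a", "a"]
        fold = [0, 0, 0, 1, 1, 1]
        p1 = _hand_preds(true, pred, fold, ["a", "b"])
        perm = rng.permutation(6)
        p2 = _hand_preds([true[i] for i in perm], [pred[i] for i in perm],
                         [fold[i] for i in perm], ["a", "b"])
        assert per_class_accuracy(p1) == per_class_accuracy(p2)

    def test_absent_class_is_undefined_not_zero(self):
        p = _hand_preds(["a"] * 2, ["a"] * 2, [0, 0], ["a", "ghost"])
        assert per_class_accuracy(p)["ghost"] is None


class TestSerialization:
    def test_model_checkpoint_round_trip(self, tmp_path):
        model = build_model(TINY_ARCH, 64, ["a", "b", "c"], seed=3)
        x = np.random.default_rng(0).random((4, 64))
        path = str(tmp_path / "m.npz")
        save_model(model, path)
        back = load_model(path)
        assert back.class_order == ["a", "b", "c"]
        assert np.allclose(back.forward(x), model.forward(x))

    def test_predictions_tsv_round_trip(self, tmp_path):
        p = _hand_preds(["a", "b", "a"], ["a", "a", "b"], [0, 1, 0], ["a", "b"])
        p.scores = np.random.default_rng(1).normal(size=(3, 2))
        path = str(tmp_path / "p.tsv")
        save_predictions(p, path)
        back = load_predictions(path)
        assert (back.true_labels == p.true_labels).all()
        assert (back.pred_labels == p.pred_labels).all()
        assert np.array_equal(back.fold, p.fold)
        assert np.allclose(back.scores, p.scores, atol=1e-5)
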