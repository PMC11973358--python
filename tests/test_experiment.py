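"""Training protocol: fold stratification, early stopping, toy learning,
hyperparameter search, leakage guard, checkpoints."""

import numpy as np
import pytest

from histonet.arch import ArchConfig
from histonet.experiment import (
    SearchSpace,
    TrainConfig,
    cross_validate,
    external_test,
    hyperparameter_search,
    load_checkpoint,
    save_checkpoint,
    stratified_kfold,
    train_model,
)
from histonet.synthdata import SyntheticConfig, SyntheticDataset, generate_arrays


def toy_cfg(**kw):
    defaults = dict(variant="baseline", base_width=4, input_size=32,
                    stage_depths=(1, 1, 1, 1), num_classes=3)
    defaults.update(kw)
    return ArchConfig(**defaults)


def two_color_set(n=40, size=32, seed=0):
    """Linearly separable 2-class toy data: red-ish vs blue-ish tiles."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n):
        lab = i % 2
        base = np.array([200, 60, 60] if lab == 0 else [60, 60, 200])
        img = np.clip(base + rng.normal(0, 12, (size, size, 3)), 0, 255)
        images.append(img.astype(np.uint8))
        labels.append(lab)
    return np.stack(images), np.array(labels)


class TestStratifiedKFold:
    def test_balanced_fold_sizes(self):
        labels = np.repeat([0, 1, 2], [40, 35, 25])
        split = stratified_kfold(labels, k=5, seed=0)
        for fold in range(5):
            _, va = split.fold_indices(fold)
            assert len(va) == 20
            # per-class proportions within +-1 of n_c/k
            for c in range(3):
                n_c = (labels[va] == c).sum()
                assert abs(n_c - (labels == c).sum() / 5) <= 1

    def test_hundred_samples_k5(self):
        split = stratified_kfold(np.tile([0, 1], 50), k=5, seed=1)
        assert all(len(split.fold_indices(f)[1]) == 20 for f in range(5))

    def test_partition_property(self):
        labels = np.repeat([0, 1, 2], 10)
        split = stratified_kfold(labels, k=5, seed=3)
        seen = np.concatenate([split.fold_indices(f)[1] for f in range(5)])
        assert sorted(seen) == list(range(30))

    def test_starved_class_error_names_class(self):
        labels = np.repeat([0, 1, 2], [90, 9, 1])
        with pytest.raises(ValueError, match="class 2"):
            stratified_kfold(labels, k=5, seed=0)

    def test_seed_determinism(self):
        labels = np.repeat([0, 1], 25)
        a = stratified_kfold(labels, k=5, seed=4).assignments
        b = stratified_kfold(labels, k=5, seed=4).assignments
        assert np.array_equal(a, b)


class TestTrainModel:
    def test_separable_toy_reaches_perfect_validation(self):
        images, labels = two_color_set()
        cfg = toy_cfg(num_classes=2)
        tcfg = TrainConfig(learning_rate=3e-3, batch_size=10, max_epochs=10,
                           patience=9, seed=0, target_val_accuracy=1.0)
        _, history = train_model(cfg, tcfg, (images[:30], labels[:30]),
                                 (images[30:], labels[30:]))
        assert max(h["val_accuracy"] for h in history) == 1.0
        assert len(history) <= tcfg.max_epochs

    def test_early_stopping_on_flat_loss(self):
        images, labels = two_color_set(n=20)
        cfg = toy_cfg(num_classes=2)
        # vanishing learning rate -> validation loss never improves after
        # the first epoch; patience=2 must stop after exactly 1 + 2 epochs
        tcfg = TrainConfig(learning_rate=1e-12, batch_size=10, max_epochs=10,
                           patience=2, seed=0)
        _, history = train_model(cfg, tcfg, (images[:10], labels[:10]),
                                 (images[10:], labels[10:]))
        assert len(history) == 3

    def test_history_confusion_consistent(self):
        images, labels = two_color_set(n=24)
        cfg = toy_cfg(num_classes=2)
        tcfg = TrainConfig(learning_rate=1e-3, batch_size=12, max_epochs=2,
                           patience=1, seed=0)
        _, history = train_model(cfg, tcfg, (images[:16], labels[:16]),
                                 (images[16:], labels[16:]))
        for row in history:
            cm = np.array(row["confusion"])
            assert np.trace(cm) / cm.sum() == pytest.approx(row["val_accuracy"])

    def test_empty_set_rejected(self):
        images, labels = two_color_set(n=10)
        with pytest.raises(ValueError):
            train_model(toy_cfg(num_classes=2), TrainConfig(max_epochs=2, patience=1),
                        (images[:0], labels[:0]), (images, labels))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(patience=100, max_epochs=100)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)


class TestCrossValidate:
    def test_five_reports_and_summary(self):
        ds = generate_arrays(
            SyntheticConfig(n_per_class=(10, 10, 10), image_size=32, seed=5)
        )
        cfg = toy_cfg()
        tcfg = TrainConfig(learning_rate=3e-3, batch_size=15, max_epochs=2,
                           patience=1, seed=0)
        result = cross_validate(cfg, tcfg, ds, k=5, seed=1)
        assert len(result["fold_reports"]) == 5
        accs = [r.accuracy for r in result["fold_reports"]]
        assert min(accs) <= result["mean_accuracy"] <= max(accs)
        assert result["all_epoch_accuracies"]  # per-epoch trajectory emitted


class TestSearch:
    @staticmethod
    def _objective(tcfg):
        # deterministic analytic surrogate with optimum at lr=1e-3
        return -abs(np.log10(tcfg.learning_rate) + 3)

    def test_single_point_space(self):
        space = SearchSpace(grids={"learning_rate": [5e-4]}, budget=1)
        best, trials = hyperparameter_search(space, self._objective)
        assert best.learning_rate == 5e-4 and len(trials) == 1

    def test_argmax_contract_and_determinism(self):
        space = SearchSpace(grids={"learning_rate": [1e-4, 1e-3, 1e-2]},
                            random_ranges={"learning_rate": (1e-5, 1e-1)},
                            budget=6)
        best, trials = hyperparameter_search(space, self._objective, seed=0)
        assert len(trials) == 6
        best_val = max(t["objective"] for t in trials)
        assert self._objective(best) == best_val
        _, trials2 = hyperparameter_search(space, self._objective, seed=0)
        assert [t["params"] for t in trials] == [t["params"] for t in trials2]

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(budget=3)


class TestExternalTest:
    def _trained(self):
        images, labels = two_color_set(n=30)
        cfg = toy_cfg(num_classes=2)
        tcfg = TrainConfig(learning_rate=3e-3, batch_size=10, max_epochs=4,
                           patience=3, seed=0, target_val_accuracy=1.0)
        model, _ = train_model(cfg, tcfg, (images[:20], labels[:20]),
                               (images[20:], labels[20:]))
        return model, cfg

    def test_leakage_guard(self):
        model, cfg = self._trained()
        images, labels = two_color_set(n=6, seed=3)
        ds = SyntheticDataset(images=images, labels=labels,
                              paths=[f"img{i}.png" for i in range(6)])
        with pytest.raises(ValueError, match="leakage"):
            external_test(model, cfg, ds, train_paths=["img2.png"])

    def test_report_on_held_out(self):
        model, cfg = self._trained()
        images, labels = two_color_set(n=10, seed=9)
        ds = SyntheticDataset(images=images, labels=labels)
        report = external_test(model, cfg, ds)
        assert report.accuracy == 1.0  # separable colors, trained to perfection
        assert len(report.per_class_precision) == 2


class TestCheckpoints:
    def test_roundtrip(self, tmp_path):
        cfg = toy_cfg()
        from histonet.arch import build_network

        model = build_network(cfg, seed=8)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        model.eval(), restored.eval()
        x = np.random.default_rng(0).normal(size=(1, 3, 32, 32)).astype(np.float32)
        assert np.array_equal(model(x).data, restored(x).data)
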