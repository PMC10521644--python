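"""Grouped folds, learning-rate schedule and the two-stage search logic."""

import dataclasses

import numpy as np
import pytest

from lca.augment import AugmentationStrategy, build_default_space
from lca.backbone import SmallCNNClassifier
from lca.search import (
    TrainConfig,
    lr_schedule,
    make_grouped_folds,
    stage1_augmentation_search,
    stage2_network_match,
    train_backbone,
)
from lca.synthetic import planted_invariance_dataset


class TestGroupedFolds:
    def test_singleton_groups_exact_split(self):
        folds = make_grouped_folds(np.arange(100), k=5, seed=0)
        for f in folds:
            assert len(f.val_ids) == 20
            assert len(f.train_ids) == 80
            assert not set(f.val_ids) & set(f.train_ids)

    def test_group_never_straddles_a_split(self):
        groups = np.repeat(np.arange(30), 3)  # 30 lesions, 3 images each
        for f in make_grouped_folds(groups, k=5, seed=1):
            val_groups = set(groups[f.val_ids])
            train_groups = set(groups[f.train_ids])
            assert not val_groups & train_groups

    def test_same_seed_identical_folds(self):
        groups = np.repeat(np.arange(40), 2)
        a = make_grouped_folds(groups, k=4, seed=9)
        b = make_grouped_folds(groups, k=4, seed=9)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.val_ids, fb.val_ids)

    def test_different_seed_different_folds(self):
        a = make_grouped_folds(np.arange(100), k=5, seed=1)
        b = make_grouped_folds(np.arange(100), k=5, seed=2)
        assert any(not np.array_equal(fa.val_ids, fb.val_ids) for fa, fb in zip(a, b))

    def test_more_folds_than_groups_rejected(self):
        with pytest.raises(ValueError):
            make_grouped_folds(np.zeros(10, dtype=int), k=5, seed=0)

    def test_every_sample_in_exactly_one_val_fold(self):
        groups = np.repeat(np.arange(17), np.arange(17) % 3 + 1)
        folds = make_grouped_folds(groups, k=4, seed=3)
        counts = np.zeros(len(groups), dtype=int)
        for f in folds:
            counts[f.val_ids] += 1
        assert np.all(counts == 1)


class TestLrSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(0, 1e-3), (5, 1e-3), (19, 1e-3), (20, 1e-4), (29, 1e-4),
         (30, 1e-5), (39, 1e-5), (45, 1e-6), (69, 1e-8)],
    )
    def test_step_decay(self, epoch, expected):
        assert lr_schedule(epoch, TrainConfig()) == pytest.approx(expected, rel=1e-12)

    def test_custom_decay_settings(self):
        cfg = TrainConfig(initial_lr=0.01, lr_decay=0.5, first_decay_epoch=2, decay_every=2)
        assert [lr_schedule(e, cfg) for e in range(6)] == [0.01, 0.01, 0.005, 0.005, 0.0025, 0.0025]


def _mock_trainer(table):
    """Trainer stub returning canned per-epoch validation BACC traces."""

    def trainer(name, probability, fold):
        return table[(name, probability)]

    return trainer


class TestStage1:
    def test_dominant_probability_selected(self):
        groups = np.arange(50)
        y = np.tile([0, 1], 25)
        space = dataclasses.replace(build_default_space(), ladder_probabilities=(0.3, 0.7))
        table = {("m", 0.3): [0.8] * 3, ("m", 0.7): [0.7] * 3}
        results, selected, _ = stage1_augmentation_search(
            None, y, groups, space, [("m", None)], TrainConfig(), seed=0,
            trainer=_mock_trainer(table),
        )
        assert selected == 0.3
        by_p = {r.probability: r for r in results}
        assert by_p[0.3].criterion == pytest.approx(0.8)
        assert by_p[0.7].criterion == pytest.approx(0.7)

    def test_criterion_is_mean_of_fold_maxima(self):
        groups = np.arange(50)
        y = np.tile([0, 1], 25)
        space = dataclasses.replace(build_default_space(), ladder_probabilities=(0.5,))
        # per-fold traces: the best epoch value is what counts
        trace = [0.2, 0.9, 0.4]
        results, _, _ = stage1_augmentation_search(
            None, y, groups, space, [("m", None)], TrainConfig(), seed=0,
            trainer=lambda n, p, f: trace,
        )
        assert results[0].criterion == pytest.approx(0.9)
        assert results[0].fold_baccs == [0.9] * 5

    def test_majority_vote_across_backbones(self):
        """Five of eight backbones peaking at one probability carries the
        vote even if the others prefer a different one."""
        groups = np.arange(40)
        y = np.tile([0, 1], 20)
        space = dataclasses.replace(build_default_space(), ladder_probabilities=(0.1, 0.3))
        table = {}
        for i in range(8):
            best = 0.3 if i < 5 else 0.1
            other = 0.1 if i < 5 else 0.3
            table[(f"b{i}", best)] = [0.85]
            table[(f"b{i}", other)] = [0.80]
        backbones = [(f"b{i}", None) for i in range(8)]
        _, selected, _ = stage1_augmentation_search(
            None, y, groups, space, backbones, TrainConfig(), seed=0,
            trainer=_mock_trainer(table),
        )
        assert selected == 0.3

    def test_vote_tie_broken_by_mean_criterion(self):
        groups = np.arange(40)
        y = np.tile([0, 1], 20)
        space = dataclasses.replace(build_default_space(), ladder_probabilities=(0.1, 0.3))
        table = {("a", 0.1): [0.9], ("a", 0.3): [0.5],
                 ("b", 0.3): [0.8], ("b", 0.1): [0.3]}
        _, selected, _ = stage1_augmentation_search(
            None, y, groups, space, [("a", None), ("b", None)], TrainConfig(), seed=0,
            trainer=_mock_trainer(table),
        )
        # votes tie 1:1; mean criterion favors 0.3? a:0.5, b:0.8 -> 0.65 vs
        # 0.1: a 0.9, b 0.3 -> 0.6; so 0.3 wins
        assert selected == 0.3


class _CannedModel:
    """Backbone stub with a fixed probability table (sklearn-clonable)."""

    def __init__(self, favourite=0):
        self.favourite = favourite

    def get_params(self, deep=True):
        return {"favourite": self.favourite}

    def set_params(self, **kw):
        self.__dict__.update(kw)
        return self

    def init_params(self, n_classes, rng):
        self.n_classes_ = n_classes
        return self

    def train_step(self, X, y, w, lr):
        return 0.0

    def predict_proba(self, X):
        out = np.full((len(X), self.n_classes_), 0.1 / (self.n_classes_ - 1))
        out[:, self.favourite] = 0.9
        return out


class TestStage2:
    def _data(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 8, 8, 3))
        y = np.tile([0, 1], 20)
        return X, y

    def test_better_backbone_recommended(self):
        X, y = self._data()
        cfg = TrainConfig(crop_size=8, eval_crops_per_axis=1, batch_size=8)
        strategy = AugmentationStrategy(build_default_space(), 0.0)
        # favourite=0 predicts class 0 always (BACC 0.5); a model predicting
        # the true labels is emulated by alternating favourites per sample is
        # not possible here, so compare degenerate vs degenerate on skewed y
        results, selected, models = stage2_network_match(
            X, y, X[:10], np.zeros(10, dtype=int), strategy,
            [("zero", _CannedModel(0)), ("one", _CannedModel(1))],
            cfg, seed=0, n_epochs=1,
        )
        by_name = {r["backbone"]: r["test_bacc"] for r in results}
        assert by_name["zero"] == 1.0 and by_name["one"] == 0.0
        assert selected == "zero"
        assert set(models) == {"zero", "one"}

    def test_single_backbone_report_complete(self):
        X, y = self._data()
        cfg = TrainConfig(crop_size=8, eval_crops_per_axis=1, batch_size=8)
        strategy = AugmentationStrategy(build_default_space(), 0.0)
        results, selected, _ = stage2_network_match(
            X, y, X[:10], y[:10], strategy, [("only", _CannedModel(0))],
            cfg, seed=0, n_epochs=3,
        )
        assert selected == "only"
        assert len(results[0]["checkpoints"]) == 3
        assert {"epoch", "test_bacc"} <= set(results[0]["checkpoints"][0])
        assert "best_epoch" in results[0]

    def test_empty_test_set_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError, match="empty test set"):
            stage2_network_match(X, y, X[:0], y[:0],
                                 AugmentationStrategy(build_default_space(), 0.0),
                                 [("m", _CannedModel())], TrainConfig(), 0)


class TestTrainBackbone:
    def test_loss_decreases_on_learnable_data(self):
        X, y, manifest = planted_invariance_dataset("shape-nuisance", n=160, seed=5)
        cfg = TrainConfig(initial_lr=5e-3, crop_size=56, eval_crops_per_axis=1, batch_size=32)
        model = SmallCNNClassifier()
        rng = np.random.default_rng(0)
        model.init_params(4, rng)
        strategy = AugmentationStrategy(build_default_space(), 0.1)
        _, trace = train_backbone(model, X, y, strategy, cfg, rng, n_epochs=4)
        losses = [t["loss"] for t in trace]
        assert losses[-1] < losses[0]

    def test_p_zero_matches_unaugmented_path(self):
        """A P=0 strategy consumes the same rng draws but never alters an
        image, so training equals the plain path image-for-image."""
        X, y, _ = planted_invariance_dataset("shape-nuisance", n=160, seed=5)
        cfg = TrainConfig(crop_size=56, eval_crops_per_axis=1, batch_size=32)
        out = []
        for _ in range(2):
            model = SmallCNNClassifier()
            rng = np.random.default_rng(1)
            model.init_params(4, rng)
            strategy = AugmentationStrategy(build_default_space(), 0.0)
            train_backbone(model, X, y, strategy, cfg, rng, n_epochs=1)
            out.append({k: v.copy() for k, v in model.params_.items()})
        for k in out[0]:
            assert np.array_equal(out[0][k], out[1][k])

    def test_backbone_contract_enforced(self):
        X, y, _ = planted_invariance_dataset("shape-nuisance", n=160, seed=5)
        with pytest.raises(TypeError, match="train_step"):
            train_backbone(object(), X, y,
                           AugmentationStrategy(build_default_space(), 0.1),
                           TrainConfig(), np.random.default_rng(0))
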