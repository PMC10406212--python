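import numpy as np
import pytest

from patchbleed.classifier import (
    CNNPatchClassifier,
    TrainingConfig,
    build_classifier,
    finetune_microbleed,
    grid_search,
    pretrain_csf,
    to_rgb_patch,
)
from patchbleed.errors import ConfigError, DataError


def separable_patches(n, seed=0, size=28, gap=40.0):
    """Balanced patch set where the first-channel center intensity alone
    predicts the class (dark center = positive)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(50.0, 3.0, size=(n, 3, size, size)).astype(np.float32)
    y = np.zeros(n, dtype=np.int64)
    y[: n // 2] = 1
    X[: n // 2, 0, size // 2 - 1 : size // 2 + 2, size // 2 - 1 : size // 2 + 2] -= gap
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestToRgbPatch:
    def test_resizes_to_224(self):
        out = to_rgb_patch(np.random.default_rng(0).normal(size=(3, 28, 28)))
        assert out.shape == (224, 224, 3)

    def test_identity_at_native_resolution(self):
        x = np.random.default_rng(1).normal(size=(3, 224, 224)).astype(np.float32)
        np.testing.assert_array_equal(to_rgb_patch(x), x.transpose(1, 2, 0))

    def test_constant_channels_stay_constant(self):
        x = np.stack([np.full((28, 28), v, dtype=np.float32) for v in (1.0, 2.0, 3.0)])
        out = to_rgb_patch(x)
        for ch, v in enumerate((1.0, 2.0, 3.0)):
            np.testing.assert_allclose(out[..., ch], v, atol=1e-5)

    def test_empty_patch_rejected(self):
        with pytest.raises(DataError):
            to_rgb_patch(np.zeros((3, 0, 0)))


class TestBuildClassifier:
    def test_head_has_two_outputs_and_probs_normalize(self):
        model = build_classifier(TrainingConfig(seed=0))
        assert model.net_.weighted_layers[-1].W.shape[0] == 2
        X = np.random.default_rng(0).normal(50, 10, size=(7, 3, 28, 28))
        p = model.predict_proba(X)
        assert p.shape == (7, 2)
        assert np.all(p >= 0) and np.all(p <= 1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_predictions(self):
        X = np.random.default_rng(2).normal(50, 10, size=(5, 3, 28, 28))
        a = build_classifier(TrainingConfig(seed=5)).predict_proba(X)
        b = build_classifier(TrainingConfig(seed=5)).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_accepts_channel_last_rgb_input(self):
        model = build_classifier(TrainingConfig(seed=0))
        rgb = np.random.default_rng(3).normal(50, 10, size=(2, 224, 224, 3))
        assert model.predict_proba(rgb).shape == (2, 2)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigError, match="not available"):
            build_classifier(TrainingConfig(backbone="resnet50"))


class TestTraining:
    def test_weights_change_after_one_step(self):
        model = build_classifier(TrainingConfig(seed=0, epochs=1))
        before = model.net_.get_weights()
        X, y = separable_patches(40, seed=1)
        model.fit(X, y, freeze=0)
        after = model.net_.get_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))

    def test_pretrain_learns_separable_fixture(self):
        X, y = separable_patches(400, seed=2)
        Xv, yv = separable_patches(200, seed=3)
        model = build_classifier(TrainingConfig(seed=1, epochs=5))
        pretrain_csf(model, X, y, Xv, yv)
        assert model.score(Xv, yv) > 0.95
        losses = [h["train_loss"] for h in model.history_]
        assert losses[-1] <= losses[0]

    def test_empty_training_set_rejected(self):
        model = build_classifier(TrainingConfig(seed=0))
        with pytest.raises(DataError):
            model.fit(np.zeros((0, 3, 28, 28)), np.zeros(0))

    def test_frozen_layers_bit_identical_after_finetune(self):
        X, y = separable_patches(80, seed=4)
        model = build_classifier(TrainingConfig(seed=2, epochs=2))
        pretrain_csf(model, X, y)
        frozen_before = [
            [p.copy() for p in layer.params()]
            for layer in model.net_.weighted_layers[:5]
        ]
        finetune_microbleed(model, X, y, freeze=5, reinit_head=False)
        for layer, before in zip(model.net_.weighted_layers[:5], frozen_before):
            for p, b in zip(layer.params(), before):
                np.testing.assert_array_equal(p, b)

    def test_no_freeze_lets_all_layers_move(self):
        X, y = separable_patches(80, seed=5)
        model = build_classifier(TrainingConfig(seed=3, epochs=2))
        before = [
            [p.copy() for p in layer.params()] for layer in model.net_.weighted_layers
        ]
        model.fit(X, y, freeze=0)
        moved = [
            any(not np.array_equal(p, b) for p, b in zip(layer.params(), snap))
            for layer, snap in zip(model.net_.weighted_layers, before)
        ]
        assert all(moved)

    def test_freeze_beyond_layer_count_rejected(self):
        X, y = separable_patches(40, seed=6)
        model = build_classifier(TrainingConfig(seed=0, epochs=1))
        with pytest.raises(ConfigError, match="exceeds"):
            model.fit(X, y, freeze=7)

    def test_fit_is_reproducible_given_seed(self):
        X, y = separable_patches(120, seed=7)
        preds = []
        for _ in range(2):
            m = build_classifier(TrainingConfig(seed=9, epochs=2))
            m.fit(X, y, freeze=0)
            preds.append(m.predict_proba(X[:10]))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = separable_patches(80, seed=8)
        model = build_classifier(TrainingConfig(seed=4, epochs=1))
        model.fit(X, y, freeze=0)
        path = tmp_path / "model.npz"
        model.save(path)
        back = CNNPatchClassifier.load(path)
        np.testing.assert_array_equal(back.predict_proba(X[:8]), model.predict_proba(X[:8]))


class TestGridSearch:
    def test_single_config_two_repeats(self):
        X, y = separable_patches(60, seed=9)
        cfg = TrainingConfig(seed=0, epochs=1)
        table = grid_search(cfg, {"learning_rate": [0.006]}, (X, y), (X, y), repeats=2)
        assert len(table) == 1
        assert table.loc[0, "repeats"] == 2
        assert 0.0 <= table.loc[0, "mean_val_accuracy"] <= 1.0

    def test_row_count_matches_swept_configs(self):
        X, y = separable_patches(60, seed=10)
        cfg = TrainingConfig(seed=0, epochs=1)
        grid = {"learning_rate": [0.002, 0.006], "mini_batch": [20, 40, 60]}
        table = grid_search(cfg, grid, (X, y), (X, y), repeats=1)
        assert len(table) == 5

    def test_unknown_parameter_rejected(self):
        X, y = separable_patches(20, seed=11)
        with pytest.raises(ConfigError):
            grid_search(TrainingConfig(), {"nope": [1]}, (X, y), (X, y), repeats=1)
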