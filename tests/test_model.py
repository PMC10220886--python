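"""CNN architecture, rotational augmentation and training contracts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from wristhar.model import (
    ArchitectureConfig,
    TrainConfig,
    TrainedModel,
    augment_batch,
    build_network,
    gram_schmidt,
    predict,
    sample_rotation,
    train,
)

SMALL = ArchitectureConfig().narrow((4, 4, 4, 4, 4, 8, 8))


class TestArchitecture:
    def test_default_receptive_field_is_112_samples_and_3p5_seconds(self):
        arch = ArchitectureConfig()
        assert arch.receptive_field_samples() == 112
        assert arch.receptive_field_s() == pytest.approx(3.5)

    def test_receptive_field_formula_accounts_for_strides(self):
        arch = ArchitectureConfig(kernel_sizes=(3,) * 7, strides=(2, 1, 1, 1, 1, 1, 1))
        # 1 + 2 + 6*(2*2) = 27
        assert arch.receptive_field_samples() == 1 + 2 + 6 * 4

    def test_dense_sizes_are_fixed(self):
        with pytest.raises(ValueError, match="dense sizes"):
            ArchitectureConfig(dense_sizes=(64, 16))

    def test_narrow_preserves_receptive_field(self):
        assert SMALL.receptive_field_samples() == 112


class TestRotationSampling:
    def test_zero_strength_is_identity_exactly(self):
        rng = np.random.default_rng(0)
        assert np.array_equal(sample_rotation(0.0, rng), np.eye(3))

    def test_sampled_rotations_are_proper_and_orthonormal(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            R = sample_rotation(0.7, rng)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            assert np.abs(R.T @ R - np.eye(3)).max() < 1e-6

    def test_matches_independent_gram_schmidt_oracle(self):
        # step-by-step projection/normalization oracle, written separately
        def gs_oracle(B):
            cols = []
            for j in range(3):
                v = B[:, j].copy()
                for q in cols:
                    v = v - np.dot(q, B[:, j]) * q
                cols.append(v / np.sqrt(np.sum(v * v)))
            return np.column_stack(cols)

        rng = np.random.default_rng(2)
        s = 0.2
        M = rng.standard_normal((3, 3))
        B = (1 - s) * np.eye(3) + s * M
        expected = gs_oracle(B)
        if np.linalg.det(expected) < 0:
            expected[:, -1] = -expected[:, -1]
        rng2 = np.random.default_rng(2)
        assert np.allclose(sample_rotation(s, rng2), expected, atol=1e-12)

    def test_small_strength_stays_near_identity(self):
        rng = np.random.default_rng(3)
        worst = max(
            np.abs(sample_rotation(1e-3, rng) - np.eye(3)).max() for _ in range(1000)
        )
        assert worst < 0.05

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            sample_rotation(1.5, np.random.default_rng(0))

    def test_gram_schmidt_rejects_degenerate_matrix(self):
        with pytest.raises(ValueError, match="degenerate"):
            gram_schmidt(np.ones((3, 3)))


class TestAugmentBatch:
    def test_eval_mode_is_bitwise_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 3, 384))
        out = augment_batch(X, 0.2, 0.03, training=False, rng=rng)
        assert np.array_equal(out, X)

    def test_degenerate_augmentation_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 3, 384))
        out = augment_batch(X, 0.0, 0.0, training=True, rng=rng)
        assert np.allclose(out, X)

    def test_rotation_preserves_per_sample_norms(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 3, 384))
        out = augment_batch(X, 0.8, 0.0, training=True, rng=rng)
        assert np.allclose(
            np.linalg.norm(out, axis=1), np.linalg.norm(X, axis=1), atol=1e-9
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match=r"\(N, 3, T\)"):
            augment_batch(np.zeros((4, 2, 384)), 0.1, 0.0, True, np.random.default_rng(0))


QUICK = TrainConfig.free_living(epochs=10, lr=5e-3, batch_size=32, decay_every=7, seed=0)


class TestTraining:
    def test_loss_halves_on_separable_two_class_data(self, two_class_windows):
        X, y = two_class_windows
        model = train((X, y), SMALL, QUICK, vocabulary=("a", "b"))
        assert model.train_log[-1]["loss"] < 0.5 * model.train_log[0]["loss"]

    def test_all_frozen_training_returns_initialization_exactly(self, two_class_windows):
        X, y = two_class_windows
        init = train((X[:8], y[:8]), SMALL,
                     dataclasses.replace(QUICK, epochs=0), vocabulary=("a", "b"))
        out = train((X, y), SMALL, QUICK, vocabulary=("a", "b"),
                    freeze_mask=tuple(init.params), initial=init)
        for name, p in init.params.items():
            for k, v in p.items():
                assert np.array_equal(out.params[name][k], v)

    def test_same_seed_same_data_identical_parameters(self, two_class_windows):
        X, y = two_class_windows
        cfg = dataclasses.replace(QUICK, epochs=3)
        a = train((X, y), SMALL, cfg, vocabulary=("a", "b"))
        b = train((X, y), SMALL, cfg, vocabulary=("a", "b"))
        for name in a.params:
            for k in a.params[name]:
                assert np.array_equal(a.params[name][k], b.params[name][k])

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty training set"):
            train((np.empty((0, 3, 384)), np.empty(0, int)), SMALL, QUICK, vocabulary=("a", "b"))

    def test_lr_schedule_decays_in_log(self, two_class_windows):
        X, y = two_class_windows
        cfg = TrainConfig.free_living(epochs=8, lr=1e-3, batch_size=64, decay_every=4, seed=0)
        model = train((X[:64], y[:64]), SMALL, cfg, vocabulary=("a", "b"))
        lrs = [row["lr"] for row in model.train_log]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[4] == pytest.approx(3e-4)

    def test_missing_classes_are_recorded(self, two_class_windows):
        X, y = two_class_windows
        only_zero = y == 0
        cfg = dataclasses.replace(QUICK, epochs=1)
        model = train((X[only_zero], y[only_zero]), SMALL, cfg, vocabulary=("a", "b"))
        assert model.provenance["missing_classes"] == ["b"]


class TestPredict:
    def test_probabilities_sum_to_one_and_are_deterministic(self, two_class_windows):
        X, y = two_class_windows
        cfg = dataclasses.replace(QUICK, epochs=2)
        model = train((X, y), SMALL, cfg, vocabulary=("a", "b"))
        dup = np.concatenate([X[:1], X[:1]])
        probs = predict(model, dup)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(probs[0], probs[1])

    def test_zeroed_head_gives_uniform_probabilities(self, two_class_windows):
        X, y = two_class_windows
        cfg = dataclasses.replace(QUICK, epochs=0)
        model = train((X[:4], y[:4]), SMALL, cfg, vocabulary=("a", "b"))
        model.params["head"]["W"][:] = 0.0
        model.params["head"]["b"][:] = 0.0
        probs = predict(model, X[:5])
        assert np.allclose(probs, 0.5, atol=1e-12)


class TestCheckpointRoundTrip:
    def test_save_load_preserves_parameters_and_metadata(self, two_class_windows, tmp_path):
        X, y = two_class_windows
        cfg = dataclasses.replace(QUICK, epochs=1)
        model = train((X[:32], y[:32]), SMALL, cfg, vocabulary=("a", "b"),
                      freeze_mask=("conv1",))
        model.save(tmp_path / "ckpt")
        back = TrainedModel.load(tmp_path / "ckpt")
        assert back.vocabulary == model.vocabulary
        assert back.freeze_mask == model.freeze_mask
        assert back.architecture == model.architecture
        for name in model.params:
            for k in model.params[name]:
                assert np.array_equal(back.params[name][k], model.params[name][k])


class TestRotationAugmentationPurpose:
    def test_augmented_model_is_more_robust_to_an_orientation_change(self, two_class_windows):
        """Rotating the whole evaluation set by a fixed R should hurt a
        rotation-augmented model less than one trained with strength 0."""
        X, y = two_class_windows
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90° about Z
        Xrot = np.einsum("ij,njt->nit", R, X)
        accs = {}
        for s in (0.0, 0.6):
            arch = dataclasses.replace(SMALL, rotation_strength=s)
            model = train((X, y), arch, QUICK, vocabulary=("a", "b"))
            p_plain = predict(model, X).argmax(axis=1)
            p_rot = predict(model, Xrot).argmax(axis=1)
            accs[s] = ((p_plain == y).mean(), (p_rot == y).mean())
        drop_plain = accs[0.0][0] - accs[0.0][1]
        drop_aug = accs[0.6][0] - accs[0.6][1]
        assert drop_aug < drop_plain
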