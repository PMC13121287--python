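"""Self-distillation core: loss oracle, EMA/centering arithmetic, training
contracts, feature extraction, PCA maps."""

import numpy as np
import pytest

from cacvit import nn
from cacvit.nn import Tensor
from cacvit.augment import AugmentParams
from cacvit.ssl_core import (
    DinoConfig,
    ViTConfig,
    VisionTransformer,
    _ema_update,
    dino_loss,
    extract_features,
    load_checkpoint,
    pca_feature_map,
    save_checkpoint,
    train_dino,
)


def tiny_dino_config(epochs=2):
    return DinoConfig(vit=ViTConfig(image_size=32, embed_dim=32, depth=1, heads=2),
                      proj_hidden=32, bottleneck=16, n_prototypes=16,
                      epochs=epochs, batch_size=8)


def tiny_dataset(rng, n=10, size=40, with_masks=True):
    ds = []
    for i in range(n):
        img = rng.uniform(-1, 1, size=(size, size))
        mask = None
        if with_masks and i % 3 == 0:
            mask = np.zeros((size, size), dtype=int)
            mask[size // 2, size // 2] = 1
        ds.append((img, mask))
    return ds


def brute_force_dino_loss(student, teacher, center, st, tt):
    """Independent pairwise summation written directly from the definition."""
    def softmax(z):
        e = np.exp(z - z.max())
        return e / e.sum()

    def log_softmax(z):
        return z - z.max() - np.log(np.exp(z - z.max()).sum())

    total, n = 0.0, 0
    for tv in range(2):
        p = softmax((teacher[tv] - center) / tt)
        for sv in range(len(student)):
            if sv == tv:
                continue
            total += -(p * log_softmax(student[sv] / st)).sum()
            n += 1
    return total / n


class TestDinoLoss:
    def test_uniform_student_against_one_hot_teacher(self):
        K = 4
        teacher = np.full((2, K), -60.0)
        teacher[:, 1] = 60.0  # one-hot after sharpening
        student = np.zeros((3, K))  # uniform
        loss = dino_loss(Tensor(student), teacher, np.zeros(K),
                         student_temp=1.0, teacher_temp=1.0)
        assert float(loss.data) == pytest.approx(np.log(4), rel=1e-6)

    def test_matching_student_achieves_target_entropy(self):
        rng = np.random.default_rng(0)
        K = 5
        teacher = rng.normal(size=(2, K))
        center = np.zeros(K)
        tt = 0.5

        def softmax(z):
            e = np.exp(z - z.max())
            return e / e.sum()

        # student logits equal to log of the sharpened target distribution
        targets = np.stack([softmax(t / tt) for t in teacher])
        entropy = -(targets * np.log(targets)).sum(axis=1)
        # views: student view v matches teacher target of the other view
        student = np.stack([np.log(targets[1]), np.log(targets[0])])
        loss = dino_loss(Tensor(student), teacher, center,
                         student_temp=1.0, teacher_temp=tt)
        assert float(loss.data) == pytest.approx(entropy.mean(), rel=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        K = 5
        student = rng.normal(size=(3, K))
        teacher = rng.normal(size=(2, K))
        center = rng.normal(size=K)
        loss = dino_loss(Tensor(student), teacher, center,
                         student_temp=0.1, teacher_temp=0.04)
        expected = brute_force_dino_loss(student, teacher, center, 0.1, 0.04)
        assert float(loss.data) == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_constant_student_shift(self):
        rng = np.random.default_rng(2)
        student = rng.normal(size=(4, 6))
        teacher = rng.normal(size=(2, 6))
        center = rng.normal(size=6)
        a = dino_loss(Tensor(student), teacher, center)
        b = dino_loss(Tensor(student + 13.7), teacher, center)
        assert float(a.data) == pytest.approx(float(b.data), rel=1e-9)

    def test_non_finite_logits_rejected(self):
        bad = np.array([[np.inf, 0.0]] * 3)
        with pytest.raises(ValueError):
            dino_loss(Tensor(bad), np.zeros((2, 2)), np.zeros(2))


class TestEmaAndCenter:
    def test_ema_update_hand_arithmetic(self):
        rng = np.random.default_rng(0)

        class Toy(nn.Module):
            def __init__(self, a, b):
                self.a = Tensor(np.array([a]), requires_grad=True)
                self.b = Tensor(np.array([b]), requires_grad=True)

        teacher, student = Toy(1.0, -2.0), Toy(3.0, 4.0)
        _ema_update(teacher, student, momentum=0.9)
        assert teacher.a.data[0] == pytest.approx(0.9 * 1.0 + 0.1 * 3.0)
        assert teacher.b.data[0] == pytest.approx(0.9 * -2.0 + 0.1 * 4.0)

    def test_center_update_is_ema_of_teacher_outputs(self):
        # the trainer's update rule, checked against direct arithmetic
        center = np.array([0.5, -0.5])
        batch = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        cm = 0.9
        updated = cm * center + (1 - cm) * batch.mean(axis=0)
        np.testing.assert_allclose(updated, [0.55, -0.35])


class TestTrainDino:
    def test_smoke_loss_finite_and_teacher_moves(self, rng):
        ds = tiny_dataset(rng)
        cfg = tiny_dino_config()
        init = VisionTransformer(cfg.vit, np.random.default_rng(0)).state_dict()
        backbone, log = train_dino(ds, cfg, label_guided=True, seed=0)
        assert np.isfinite(log["loss"]).all()
        moved = any(not np.allclose(backbone.state_dict()[k], init[k])
                    for k in init)
        assert moved

    def test_deterministic_under_seed(self, rng):
        ds = tiny_dataset(rng)
        cfg = tiny_dino_config()
        _, log_a = train_dino(ds, cfg, label_guided=True, seed=3)
        _, log_b = train_dino(ds, cfg, label_guided=True, seed=3)
        assert log_a["loss"] == log_b["loss"]

    def test_label_guided_false_builds_no_guided_crops(self, rng):
        ds = tiny_dataset(rng, with_masks=True)
        cfg = tiny_dino_config()
        _, log = train_dino(ds, cfg, label_guided=False, seed=0)
        assert log["guided_crop_count"] == 0
        _, log_lg = train_dino(ds, cfg, label_guided=True, seed=0)
        assert log_lg["guided_crop_count"] > 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_dino([], tiny_dino_config(), seed=0)


class TestExtractFeatures:
    @pytest.fixture(scope="class")
    def backbone(self):
        return VisionTransformer(ViTConfig(image_size=32, embed_dim=32, depth=1,
                                           heads=2), np.random.default_rng(0))

    def test_feature_dimension_matches_embedding(self, backbone, rng):
        slices = [rng.uniform(-1, 1, size=(32, 32)) for _ in range(4)]
        fm = extract_features(backbone, slices)
        assert fm.values.shape == (4, 32)
        assert fm.source == "cls_token"

    def test_identical_slices_identical_rows(self, backbone, rng):
        s = rng.uniform(-1, 1, size=(32, 32))
        fm = extract_features(backbone, [s, s.copy()])
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_batched_equals_one_by_one(self, backbone, rng):
        slices = [rng.uniform(-1, 1, size=(32, 32)) for _ in range(5)]
        batched = extract_features(backbone, slices, batch_size=5).values
        single = np.concatenate([
            extract_features(backbone, [s]).values for s in slices])
        np.testing.assert_allclose(batched, single, rtol=1e-5, atol=1e-6)

    def test_save_load_round_trip(self, backbone, rng, tmp_path):
        slices = [rng.uniform(-1, 1, size=(32, 32)) for _ in range(3)]
        fm = extract_features(backbone, slices,
                              row_index=[("p1", 0), ("p1", 1), ("p2", 0)])
        fm.save(tmp_path / "feats.npy")
        back = fm.load(tmp_path / "feats.npy")
        np.testing.assert_array_equal(back.values, fm.values)
        assert back.row_index == fm.row_index

    def test_native_resolution_used_when_compatible(self, backbone, rng):
        # 40x40 is not divisible by patch 8; falls back to the training size
        fm = extract_features(backbone, [rng.uniform(-1, 1, size=(40, 40))])
        assert fm.values.shape == (1, 32)
        # 48x48 is divisible: positional embeddings are interpolated
        fm = extract_features(backbone, [rng.uniform(-1, 1, size=(48, 48))])
        assert fm.values.shape == (1, 32)


class TestPcaFeatureMap:
    @pytest.fixture(scope="class")
    def backbone(self):
        return VisionTransformer(ViTConfig(image_size=32, embed_dim=32, depth=1,
                                           heads=2), np.random.default_rng(1))

    def test_output_spatial_size_matches_input(self, backbone, rng):
        img = rng.uniform(-1, 1, size=(32, 32))
        out = pca_feature_map(backbone, img, n_components=3)
        assert out.shape == (32, 32, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_constant_input_gives_zero_map(self, backbone):
        out = pca_feature_map(backbone, np.zeros((32, 32)))
        np.testing.assert_array_equal(out, 0.0)

    def test_component_variance_ordering(self, backbone, rng):
        img = rng.uniform(-1, 1, size=(32, 32))
        cfg = backbone.config
        from cacvit.ssl_core import _prepare_batch

        with nn.no_grad():
            tokens = backbone.patch_embeddings(_prepare_batch([img], 32)).data[0]
        centered = tokens - tokens.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        comps = centered @ vt[:3].T
        assert comps[:, 0].var() >= comps[:, 1].var() >= comps[:, 2].var()

    def test_too_many_components_rejected(self, backbone, rng):
        with pytest.raises(ValueError):
            pca_feature_map(backbone, np.zeros((32, 32)), n_components=999)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        cfg = tiny_dino_config()
        backbone = VisionTransformer(cfg.vit, np.random.default_rng(5))
        save_checkpoint(backbone, cfg, epoch=7, path=tmp_path / "ck.npz")
        loaded, epoch = load_checkpoint(tmp_path / "ck.npz")
        assert epoch == 7
        s = rng.uniform(-1, 1, size=(32, 32))
        a = extract_features(backbone, [s]).values
        b = extract_features(loaded, [s]).values
        np.testing.assert_allclose(a, b, atol=1e-7)
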