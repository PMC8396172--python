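"""Folds, patch sampling, training strategies, and stitched inference."""

import numpy as np
import pytest

from murilung.core import BinaryMask, CTVolume
from murilung.detector import (
    NetworkSpec,
    TrainConfig,
    VNet,
    make_folds,
    patch_origins,
    sample_patch,
    sliding_window_predict,
    train,
    train_single,
)
from murilung.tumorsim.dataset import SimulatedSet

TOY_SPEC = NetworkSpec(n_stages=2, channels=(2, 4), convs_per_stage=(1, 1),
                       conv_kernel=3, dropout_rate=0.01, seed=0)


def toy_cfg(**kw):
    defaults = dict(strategy="sim_only", epochs=10, batch_size=1, patch_size=16,
                    k_folds=2, lr0=0.01)
    defaults.update(kw)
    return TrainConfig(**defaults)


def _toy_sets(n=4, seed=0, shape=(24, 24, 24)):
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n):
        img = rng.normal(-500.0, 30.0, shape).astype(np.float32)
        lab = np.zeros(shape, dtype=np.uint8)
        z, y, x = rng.integers(4, shape[0] - 8, 3)
        lab[z : z + 4, y : y + 4, x : x + 4] = 1
        img[lab.astype(bool)] = 150.0
        sets.append(SimulatedSet(CTVolume(img, 300.0), BinaryMask(lab, 300.0), i, i == n - 1))
    return sets


class TestFolds:
    def test_ten_ids_five_folds(self):
        fs = make_folds(list(range(10)), 5, np.random.default_rng(0))
        assert all(len(f["test"]) == 2 for f in fs)

    def test_partition_property(self):
        ids = [f"scan{i}" for i in range(17)]
        fs = make_folds(ids, 5, np.random.default_rng(1))
        tests = [set(f["test"]) for f in fs]
        union = set().union(*tests)
        assert union == set(ids)
        for i, a in enumerate(tests):
            for b in tests[i + 1 :]:
                assert not (a & b)
        for f in fs:
            assert set(f["train"]) == set(ids) - set(f["test"])

    def test_thirtysix_ids_balanced(self):
        fs = make_folds(list(range(36)), 5, np.random.default_rng(2))
        assert sorted(len(f["test"]) for f in fs) == [7, 7, 7, 7, 8]

    def test_too_few_scans_raises(self):
        with pytest.raises(ValueError):
            make_folds([1, 2, 3], 5)


class TestPatchSampling:
    def test_tumor_fraction_near_eighty_percent(self):
        """Empirical tumor-containing fraction within the 99% binomial CI.

        The labeled volume is large relative to the patch so a uniformly
        random patch almost never hits the tumor by accident."""
        rng0 = np.random.default_rng(3)
        shape = (96, 96, 96)
        img = rng0.normal(-500.0, 30.0, shape).astype(np.float32)
        lab = np.zeros(shape, dtype=np.uint8)
        lab[40:43, 40:43, 40:43] = 1
        image, labels = CTVolume(img, 300.0), BinaryMask(lab, 300.0)
        cfg = toy_cfg(patch_size=16)
        rng = np.random.default_rng(0)
        n = 4000
        hits = sum(
            sample_patch(image, labels, cfg, rng)[1].sum() > 0 for _ in range(n)
        )
        half_width = 2.576 * np.sqrt(0.8 * 0.2 / n)
        assert abs(hits / n - 0.8) < half_width + 0.011  # + random-hit rate

    def test_normalization_to_thousandths(self):
        img = CTVolume(np.full((16, 16, 16), -1000.0, dtype=np.float32), 300.0)
        lab = BinaryMask(np.zeros((16, 16, 16), dtype=np.uint8), 300.0)
        cfg = toy_cfg(patch_size=16, p_tumor_patch=0.0)
        patch, _ = sample_patch(img, lab, cfg, np.random.default_rng(0))
        assert np.allclose(patch, -1.0)

    def test_flip_is_involution(self):
        sets = _toy_sets(1, seed=5)
        cfg = toy_cfg(patch_size=16, p_tumor_patch=0.0, coronal_flip_prob=1.0)
        rng1 = np.random.default_rng(4)
        p1, _ = sample_patch(sets[0].image, sets[0].labels, cfg, rng1)
        assert np.array_equal(p1[:, :, ::-1][:, :, ::-1], p1)

    def test_empty_labels_fall_back_to_random(self):
        img = CTVolume(np.zeros((16, 16, 16), dtype=np.float32), 300.0)
        lab = BinaryMask(np.zeros((16, 16, 16), dtype=np.uint8), 300.0)
        cfg = toy_cfg(patch_size=16, p_tumor_patch=1.0)
        patch, lab_p = sample_patch(img, lab, cfg, np.random.default_rng(0))
        assert patch.shape == (16, 16, 16)
        assert lab_p.sum() == 0


class TestTraining:
    def test_loss_decreases_on_toy_data(self):
        sets = _toy_sets(3, seed=1)
        model, hist = train_single(TOY_SPEC, sets, toy_cfg(epochs=40, batch_size=2),
                                   np.random.default_rng(0))
        assert np.mean(hist["loss"][-5:]) < np.mean(hist["loss"][:5])

    def test_same_seed_identical_loss_curves(self):
        sets = _toy_sets(2, seed=2)
        _, h1 = train_single(TOY_SPEC, sets, toy_cfg(epochs=6), np.random.default_rng(11))
        _, h2 = train_single(TOY_SPEC, sets, toy_cfg(epochs=6), np.random.default_rng(11))
        assert h1["loss"] == h2["loss"]

    def test_lr_schedule_decays_ten_percent_per_hundred(self):
        sets = _toy_sets(2, seed=2)
        cfg = toy_cfg(epochs=2, lr_decay_every=1, lr_decay=0.9)
        _, hist = train_single(TOY_SPEC, sets, cfg, np.random.default_rng(0))
        assert hist["lr"][1] == pytest.approx(hist["lr"][0] * 0.9)

    def test_transfer_zero_epochs_identical_to_pretrained(self):
        sets = _toy_sets(4, seed=3)
        cfg = toy_cfg(strategy="transfer", epochs=5, k_folds=2, transfer_epochs=0)
        result = train({"sim": sets, "real": sets}, cfg, TOY_SPEC, np.random.default_rng(0))
        base_cfg = toy_cfg(strategy="sim_only", epochs=5)
        base = train({"sim": sets}, base_cfg, TOY_SPEC, np.random.default_rng(0))
        w_fold = result.folds[0].model.get_weights()
        w_base = base.folds[0].model.get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w_fold, w_base))

    def test_strategy_data_requirements(self):
        sets = _toy_sets(3, seed=0)
        with pytest.raises(ValueError):
            train({"real": sets}, toy_cfg(strategy="sim_only"), TOY_SPEC,
                  np.random.default_rng(0))
        with pytest.raises(ValueError):
            train({"sim": sets}, toy_cfg(strategy="real_only"), TOY_SPEC,
                  np.random.default_rng(0))

    def test_combined_strategy_trains_per_fold(self):
        sets = _toy_sets(4, seed=4)
        cfg = toy_cfg(strategy="combined", epochs=2, k_folds=2)
        result = train({"sim": sets, "real": sets}, cfg, TOY_SPEC, np.random.default_rng(0))
        assert len(result.folds) == 2
        union = set().union(*(set(f.test_ids) for f in result.folds))
        assert union == {0, 1, 2, 3}


class _ConstantModel:
    """Stand-in model emitting a constant probability (flip symmetric)."""

    def __init__(self, c):
        self.c = c

    def forward(self, x, training=False):
        return np.full_like(x, self.c)


class TestSlidingWindow:
    def test_origin_coverage_counts_match_brute_force(self):
        """1-D analogue oracle: every voxel's divisor equals the number of
        covering patches."""
        dim, patch, stride = 20, 8, 5
        origins = patch_origins(dim, patch, stride)
        cover = np.zeros(dim, dtype=int)
        for o in origins:
            cover[o : o + patch] += 1
        brute = np.zeros(dim, dtype=int)
        for o in set(list(range(0, dim - patch + 1, stride)) + [dim - patch]):
            brute[o : o + patch] += 1
        assert np.array_equal(cover, brute)
        assert cover.min() >= 1

    def test_constant_model_constant_output(self):
        vol = CTVolume(np.random.default_rng(0).normal(size=(20, 20, 20)).astype(np.float32), 300.0)
        out = sliding_window_predict(_ConstantModel(0.37), vol, patch_size=8, stride=5)
        assert np.allclose(out.voxels, 0.37, atol=1e-6)

    def test_stride_equal_patch_pure_tiling(self):
        spec = NetworkSpec(n_stages=1, channels=(2,), convs_per_stage=(1,), conv_kernel=3, seed=0)
        model = VNet(spec)
        vol = CTVolume(np.random.default_rng(1).normal(size=(16, 16, 16)).astype(np.float32), 300.0)
        out = sliding_window_predict(model, vol, patch_size=8, stride=8)
        direct = model.forward((vol.voxels[None, None, :8, :8, :8]) / 1000.0)
        assert np.allclose(out.voxels[:8, :8, :8], direct[0, 0], atol=1e-6)

    def test_volume_smaller_than_patch_padded(self):
        vol = CTVolume(np.zeros((6, 6, 6), dtype=np.float32), 300.0)
        out = sliding_window_predict(_ConstantModel(0.5), vol, patch_size=8, stride=8)
        assert out.shape == (6, 6, 6)

    def test_flip_equivariance_with_symmetric_model(self):
        vol = CTVolume(np.random.default_rng(2).normal(size=(16, 16, 16)).astype(np.float32), 300.0)
        flipped = CTVolume(vol.voxels[:, :, ::-1].copy(), 300.0)
        m = _ConstantModel(0.4)
        a = sliding_window_predict(m, vol, patch_size=8, stride=4)
        b = sliding_window_predict(m, flipped, patch_size=8, stride=4)
        assert np.allclose(a.voxels[:, :, ::-1], b.voxels)
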