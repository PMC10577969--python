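import numpy as np
import pytest

from priorseg import (
    ImageVolume,
    TrainConfig,
    build_unet,
    dice_loss,
    make_folds,
    predict,
    soft_dsc,
    train,
)
from priorseg.unet_model import _dice_loss_grad

TINY = dict(base_channels=2, depth=2, input_shape=(16, 16, 8))


class TestBuildUnet:
    def test_output_shape_and_range(self, rng):
        net = build_unet(TrainConfig(seed=0, **TINY))
        x = rng.random((2, 16, 16, 8)).astype(np.float32)
        prob = net.forward(x)
        assert prob.shape == (16, 16, 8)
        assert np.all(prob > 0.0) and np.all(prob < 1.0)

    def test_different_seeds_different_weights(self):
        a = build_unet(TrainConfig(seed=1, **TINY))
        b = build_unet(TrainConfig(seed=2, **TINY))
        assert not np.array_equal(a.params["enc0.w"], b.params["enc0.w"])

    def test_indivisible_input_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_unet(TrainConfig(base_channels=2, depth=2, input_shape=(15, 16, 8)))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_unet(TrainConfig(seed=3, **TINY))
        path = str(tmp_path / "ckpt.npz")
        net.save(path)
        back = net.load(path)
        x = rng.random((2, 16, 16, 8)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), back.forward(x))


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self, rng):
        t = (rng.random((8, 8, 4)) > 0.6).astype(np.float64)
        assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-3)

    def test_total_mismatch_near_one(self, rng):
        t = (rng.random((8, 8, 4)) > 0.6).astype(np.float64)
        assert dice_loss(1.0 - t, t) == pytest.approx(1.0, abs=0.01)

    def test_uniform_half_probability_closed_form(self):
        t = np.zeros((4, 4, 2))
        t[:2] = 1.0  # half foreground
        p = np.full_like(t, 0.5)
        n = t.size
        eps = 1.0
        expected = 1.0 - (2 * 0.5 * (n / 2) + eps) / (0.5 * n + n / 2 + eps)
        assert dice_loss(p, t) == pytest.approx(expected)

    def test_loss_plus_soft_dsc_is_one(self, rng):
        p = rng.random((6, 6, 3))
        t = (rng.random((6, 6, 3)) > 0.5).astype(float)
        assert dice_loss(p, t) + soft_dsc(p, t) == pytest.approx(1.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.2, 0.8, (5, 5, 2))
        t = (rng.random((5, 5, 2)) > 0.5).astype(float)
        g = _dice_loss_grad(p, t)
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            pp = p.copy()
            pp[idx] += eps
            num = (dice_loss(pp, t) - dice_loss(p, t)) / eps
            assert g[idx] == pytest.approx(num, rel=1e-3, abs=1e-9)


class TestMakeFolds:
    def test_110_cases_5_folds_of_22(self):
        split = make_folds([f"p{i}" for i in range(110)], k=5, seed=0)
        sizes = [len(split.fold_ids(f)) for f in range(5)]
        assert sizes == [22] * 5

    def test_partition_no_repeats(self):
        ids = [f"c{i}" for i in range(10)]
        split = make_folds(ids, k=5, seed=3)
        all_ids = [i for f in range(5) for i in split.fold_ids(f)]
        assert sorted(all_ids) == sorted(ids)
        assert all(len(split.fold_ids(f)) == 2 for f in range(5))

    def test_deterministic_given_seed(self):
        ids = list(range(20))
        a = make_folds(ids, 4, seed=9)
        b = make_folds(ids, 4, seed=9)
        c = make_folds(ids, 4, seed=10)
        assert a.assignments == b.assignments
        assert a.assignments != c.assignments

    def test_k_larger_than_cases_rejected(self):
        with pytest.raises(ValueError):
            make_folds([1, 2, 3], k=5, seed=0)


class TestTraining:
    def test_learning_rate_schedule(self):
        cfg = TrainConfig(**TINY)
        assert cfg.lr_at_epoch(1) == pytest.approx(5e-4)
        assert cfg.lr_at_epoch(3) == pytest.approx(5e-4 * 0.95 ** 2)

    def test_loss_decreases_on_easy_phantoms(self, rng):
        cfg = TrainConfig(seed=4, learning_rate=0.05, max_epochs=5, batch_size=4, **TINY)
        net = build_unet(cfg)
        cases = []
        for _ in range(8):
            t = np.zeros((16, 16, 8), np.float32)
            i, j = rng.integers(3, 9, 2)
            t[i : i + 6, j : j + 6, 2:6] = 1
            x = np.stack([t * 0.7 + 0.1, t * 0.8 + 0.05]).astype(np.float32)
            cases.append((x, t))
        net, hist = train(net, cases, cfg)
        assert hist["epoch_loss"][-1] < hist["epoch_loss"][0]
        assert np.isclose(hist["lr"][1], 0.05 * 0.95)

    def test_same_seed_identical_history(self):
        t = np.zeros((16, 16, 8), np.float32)
        t[4:10, 4:10, 2:5] = 1
        x = np.stack([t, t * 0.5]).astype(np.float32)
        histories = []
        for _ in range(2):
            cfg = TrainConfig(seed=7, max_epochs=3, **TINY)
            _, hist = train(build_unet(cfg), [(x, t)], cfg)
            histories.append(hist["epoch_loss"])
        assert histories[0] == histories[1]

    def test_empty_training_set_rejected(self):
        cfg = TrainConfig(**TINY)
        with pytest.raises(ValueError):
            train(build_unet(cfg), [], cfg)

    def test_overfit_single_case_reaches_high_dsc(self):
        cfg = TrainConfig(
            seed=5, learning_rate=0.1, max_epochs=40, batch_size=1, **TINY
        )
        net = build_unet(cfg)
        t = np.zeros((16, 16, 8), np.float32)
        t[4:12, 5:11, 2:6] = 1
        x = np.stack([t * 0.6 + 0.2, t * 0.9 + 0.05]).astype(np.float32)
        net, _ = train(net, [(x, t)], cfg)
        pre = ImageVolume(x[0], (1, 1, 1))
        post = ImageVolume(x[1], (1, 1, 1))
        mask = predict(net, pre, post)
        inter = np.logical_and(mask.voxels, t > 0).sum()
        dsc_val = 2 * inter / (mask.n_foreground + t.sum())
        assert dsc_val >= 0.85


class TestPredict:
    def test_threshold_on_handbuilt_probability_grid(self, monkeypatch, rng):
        net = build_unet(TrainConfig(seed=0, **TINY))
        prob = np.full((16, 16, 8), 0.2)
        prob[3:7, 3:7, 2:5] = 0.9
        monkeypatch.setattr(net, "forward", lambda x, keep_cache=False: prob)
        vol = ImageVolume(np.zeros((16, 16, 8), np.float32), (1, 1, 1))
        mask = predict(net, vol, vol)
        expected = prob >= 0.5
        assert np.array_equal(mask.voxels, expected)

    def test_empty_prediction_returned_empty(self, monkeypatch):
        net = build_unet(TrainConfig(seed=0, **TINY))
        monkeypatch.setattr(
            net, "forward", lambda x, keep_cache=False: np.full((16, 16, 8), 0.1)
        )
        vol = ImageVolume(np.zeros((16, 16, 8), np.float32), (1, 1, 1))
        mask = predict(net, vol, vol)
        assert mask.n_foreground == 0

    def test_largest_component_kept(self, monkeypatch):
        net = build_unet(TrainConfig(seed=0, **TINY))
        prob = np.full((16, 16, 8), 0.1)
        prob[2:8, 2:8, 2:6] = 0.9  # large blob
        prob[12:14, 12:14, 6:8] = 0.9  # small distant blob
        monkeypatch.setattr(net, "forward", lambda x, keep_cache=False: prob)
        vol = ImageVolume(np.zeros((16, 16, 8), np.float32), (1, 1, 1))
        mask = predict(net, vol, vol)
        assert mask.voxels[4, 4, 4]
        assert not mask.voxels[12, 12, 6]
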