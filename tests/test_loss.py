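"""Contextual and combined loss tests, with a brute-force oracle."""

import numpy as np
import pytest

from compunet import LossConfig, combined_loss, contextual_loss, extract_features
from compunet.loss import (RandomConvExtractor, combined_loss_terms,
                           contextual_loss_t, make_extractor)
from compunet.ndl import Tensor


def cx_bruteforce(pred, target, h, eps):
    """Direct per-element transcription of the contextual-loss formula."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    pred = pred - pred.mean(axis=0)
    target = target - target.mean(axis=0)

    def unit(v):
        n = np.sqrt((v * v).sum())
        return v / max(n, 1e-12)

    npf, ntf = len(pred), len(target)
    d = np.empty((npf, ntf))
    for i in range(npf):
        for j in range(ntf):
            d[i, j] = 1.0 - float(unit(pred[i]) @ unit(target[j]))
    dt = np.empty_like(d)
    for i in range(npf):
        m = min(d[i, k] for k in range(ntf))
        for j in range(ntf):
            dt[i, j] = d[i, j] / (m + eps)
    w = np.exp((1.0 - dt) / h)
    cx = w / w.sum(axis=1, keepdims=True)
    score = sum(max(cx[i, j] for i in range(npf)) for j in range(ntf))
    return -np.log(score / npf)


CASES = [
    # hand-enumerable 2-feature instance
    (np.array([[1.0, 0.0], [0.0, 1.0]]),
     np.array([[0.9, 0.1], [-0.2, 1.1]])),
    # 3 predicted vs 2 target features (unequal sizes)
    (np.array([[1.0, 2.0, 0.0], [0.0, -1.0, 1.0], [2.0, 2.0, 2.0]]),
     np.array([[1.0, 1.9, 0.1], [0.5, -1.0, 0.8]])),
]


class TestContextualLoss:
    @pytest.mark.parametrize("pred,target", CASES)
    def test_matches_bruteforce_transcription(self, pred, target):
        cfg = LossConfig(bandwidth_h=0.5, epsilon=1e-5)
        expected = cx_bruteforce(pred, target, cfg.bandwidth_h, cfg.epsilon)
        assert abs(contextual_loss(pred, target, cfg) - expected) < 1e-10

    @pytest.mark.parametrize("n,d,seed", [(5, 3, 0), (16, 4, 1), (40, 8, 2)])
    def test_matches_bruteforce_on_random_sets(self, n, d, seed):
        rng = np.random.default_rng(seed)
        pred, target = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        cfg = LossConfig()
        expected = cx_bruteforce(pred, target, cfg.bandwidth_h, cfg.epsilon)
        assert abs(contextual_loss(pred, target, cfg) - expected) < 1e-10

    def test_identical_sets_give_zero(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=(30, 5))
        assert contextual_loss(f, f, LossConfig()) <= 1e-6

    def test_invariant_under_target_permutation(self):
        rng = np.random.default_rng(4)
        pred, target = rng.normal(size=(12, 4)), rng.normal(size=(12, 4))
        cfg = LossConfig()
        a = contextual_loss(pred, target, cfg)
        b = contextual_loss(pred, target[rng.permutation(12)], cfg)
        assert abs(a - b) < 1e-12

    def test_row_normalisation_sums_to_one(self):
        """Every row of the CX affinity matrix sums to 1 by construction."""
        rng = np.random.default_rng(5)
        pred, target = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        cfg = LossConfig()
        p = Tensor(pred - pred.mean(0))
        t = Tensor(target - target.mean(0))
        pn = p.data / np.linalg.norm(p.data, axis=1, keepdims=True)
        tn = t.data / np.linalg.norm(t.data, axis=1, keepdims=True)
        d = 1.0 - pn @ tn.T
        dt = d / (d.min(axis=1, keepdims=True) + cfg.epsilon)
        w = np.exp((1.0 - dt) / cfg.bandwidth_h)
        cx = w / w.sum(axis=1, keepdims=True)
        assert np.allclose(cx.sum(axis=1), 1.0, atol=1e-12)

    def test_degenerate_sets_rejected(self):
        cfg = LossConfig()
        flat = np.ones((6, 3))
        with pytest.raises(ValueError, match="zero norm"):
            contextual_loss(flat, flat + 1.0, cfg)
        with pytest.raises(ValueError, match="dimensionality"):
            contextual_loss(np.random.default_rng(0).normal(size=(4, 3)),
                            np.random.default_rng(1).normal(size=(4, 5)), cfg)

    def test_subsampling_is_seeded(self):
        rng = np.random.default_rng(6)
        pred = rng.normal(size=(500, 4))
        target = rng.normal(size=(500, 4))
        cfg = LossConfig(max_features=64, seed=9)
        assert contextual_loss(pred, target, cfg) == \
            contextual_loss(pred, target, cfg)


class TestExtractors:
    def test_raw_patch_count_and_dimension(self):
        img = np.random.default_rng(0).normal(size=(10, 12))
        cfg = LossConfig(extractor="raw-patches", patch_size=3)
        sets = extract_features(img, cfg)
        assert len(sets) == 1
        assert sets[0].features.shape == ((10 - 2) * (12 - 2), 9)

    def test_random_conv_deterministic(self):
        img = np.random.default_rng(1).normal(size=(32, 32))
        cfg = LossConfig(seed=7)
        a = extract_features(img, cfg)
        b = extract_features(img, cfg)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.features, fb.features)
            assert fa.layer_id == fb.layer_id

    def test_identical_images_identical_features(self):
        img = np.random.default_rng(2).normal(size=(24, 24))
        cfg = LossConfig()
        a = extract_features(img.copy(), cfg)
        b = extract_features(img.copy(), cfg)
        assert all(np.array_equal(x.features, y.features)
                   for x, y in zip(a, b))

    def test_image_smaller_than_receptive_field_rejected(self):
        with pytest.raises(ValueError, match="receptive field"):
            extract_features(np.zeros((4, 4)), LossConfig())

    def test_batched_extraction_matches_single(self):
        cfg = LossConfig()
        ext = make_extractor(cfg)
        imgs = np.random.default_rng(3).normal(size=(3, 1, 16, 16)) \
            .astype(np.float32)
        batched = ext.forward_batch(Tensor(imgs))
        for b in range(3):
            single = ext(Tensor(imgs[b, 0]))
            for fb, fs in zip(batched, single):
                assert np.allclose(fb.data[b], fs.data, atol=1e-6)


class TestCombinedLoss:
    def test_zero_for_identical_slices(self, phantom):
        """Identical non-degenerate slices score ~0.  (A slice with large
        exactly-constant regions yields duplicate features, which the
        contextual formula discounts — hence the added texture.)"""
        from compunet.volume import normalize
        rng = np.random.default_rng(0)
        sl = normalize(phantom.data[32]) + rng.normal(0, 0.05, (64, 64))
        assert combined_loss(sl, sl.copy(), LossConfig()) <= 1e-6

    def test_reduces_to_l1_when_lambda_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(20, 20)), rng.normal(size=(20, 20))
        cfg = LossConfig(lambda_cx=0.0)
        assert abs(combined_loss(a, b, cfg) - np.abs(a - b).mean()) < 1e-12

    def test_shifted_slice_closer_than_unrelated(self, phantom):
        """The CX term sees a 2-pixel shift as far more similar than an
        unrelated slice with the same histogram."""
        from compunet.volume import normalize
        sl = normalize(phantom.data[32])
        rng = np.random.default_rng(1)
        sl = sl + rng.normal(0, 0.01, sl.shape)
        shifted = np.roll(sl, 2, axis=1)
        unrelated = rng.permutation(sl.ravel()).reshape(sl.shape)
        cfg = LossConfig(lambda_cx=1.0)
        _, _, cx_shift = combined_loss_terms(sl, shifted, cfg)
        _, _, cx_unrel = combined_loss_terms(sl, unrelated, cfg)
        assert cx_shift < cx_unrel

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            combined_loss(np.zeros((8, 8)), np.zeros((8, 9)),
                          LossConfig(lambda_cx=0.0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(lambda_cx=-1.0).validate()
        with pytest.raises(ValueError):
            LossConfig(bandwidth_h=0.0).validate()
        with pytest.raises(ValueError):
            LossConfig(extractor="vgg19").validate()

    def test_loss_gradient_matches_finite_differences(self):
        """Spot-check d(loss)/d(pred) on a handful of pixels."""
        rng = np.random.default_rng(2)
        pred = rng.uniform(0, 1, (16, 16))
        target = rng.uniform(0, 1, (16, 16))
        cfg = LossConfig(lambda_cx=0.5, max_features=64)
        ext = make_extractor(cfg)

        from compunet.loss import combined_loss_t

        def value(p):
            total, _, _ = combined_loss_t(Tensor(p), Tensor(target), cfg, ext)
            return total.item()

        t = Tensor(pred, requires_grad=True)
        total, _, _ = combined_loss_t(t, Tensor(target), cfg, ext)
        total.backward()
        eps = 1e-6
        for (i, j) in [(0, 0), (5, 7), (11, 3), (15, 15), (8, 8)]:
            hi, lo = pred.copy(), pred.copy()
            hi[i, j] += eps
            lo[i, j] -= eps
            num = (value(hi) - value(lo)) / (2 * eps)
            assert abs(num - t.grad[i, j]) < 1e-4
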