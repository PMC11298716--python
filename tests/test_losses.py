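"""Loss functions against closed forms and naive scalar-loop oracles."""

import math

import numpy as np
import pytest

from semiseg.autograd import Tensor
from semiseg.fixtures import oracle_pseudo_loss, oracle_supervised_loss
from semiseg.losses import (LossConfig, consistency_loss, cross_entropy_loss,
                            perturb_features, pseudo_label_loss, rampup_weight,
                            reconstruction_loss, soft_dice_loss,
                            supervised_loss, total_loss)
from semiseg.nn import Conv2d

from conftest import random_probs


class TestSupervisedLoss:
    def test_perfect_prediction_is_zero(self):
        labels = np.array([[[0, 1], [1, 0]]])
        probs = np.zeros((1, 2, 2, 2))
        for i in range(2):
            for j in range(2):
                probs[0, labels[0, i, j], i, j] = 1.0
        assert float(supervised_loss(probs, labels)) < 1e-4  # Dice smoothing eps

    def test_single_pixel_half_confidence_is_ln2_plus_dice(self):
        probs = np.array([0.5, 0.5]).reshape(1, 2, 1, 1)
        labels = np.ones((1, 1, 1), dtype=int)
        ce = float(cross_entropy_loss(probs, labels))
        assert ce == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize("n,c,h,w", [(1, 2, 4, 4), (3, 3, 8, 8), (2, 4, 5, 7)])
    def test_matches_scalar_loop_oracle(self, rng, n, c, h, w):
        probs = random_probs(rng, n, c, h, w)
        labels = rng.integers(0, c, size=(n, h, w))
        assert float(supervised_loss(probs, labels)) == pytest.approx(
            oracle_supervised_loss(probs, labels), abs=1e-9)

    def test_zero_slices_rejected(self):
        with pytest.raises(ValueError):
            supervised_loss(np.zeros((0, 2, 4, 4)), np.zeros((0, 4, 4), int))


class TestSoftDice:
    def test_half_overlap_toy(self):
        # prediction area 4, label area 4, overlap 2 -> loss 1 - 4/8
        probs = np.zeros((1, 2, 4, 4))
        probs[0, 1, 0, :] = 1.0          # predicts row 0
        probs[0, 0] = 1.0 - probs[0, 1]
        labels = np.zeros((1, 4, 4), int)
        labels[0, 0, 2:] = 1             # overlap 2
        labels[0, 1, 2:] = 1
        assert float(soft_dice_loss(probs, labels)) == pytest.approx(0.5, abs=1e-4)

    def test_disjoint_near_one(self):
        probs = np.zeros((1, 2, 8, 8))
        probs[0, 1, :4] = 1.0
        probs[0, 0] = 1.0 - probs[0, 1]
        labels = np.zeros((1, 8, 8), int)
        labels[0, 6:] = 1
        assert float(soft_dice_loss(probs, labels)) == pytest.approx(1.0, abs=1e-3)


class TestPseudoLabelLoss:
    def test_all_unconfident_gives_zero(self, rng):
        probs = np.full((1, 2, 3, 3), 0.5)
        loss, n_conf = pseudo_label_loss(probs, probs, tau1=0.9)
        assert float(loss) == 0.0 and n_conf == 0

    def test_single_pixel_closed_form(self):
        probs = np.array([0.95, 0.05]).reshape(1, 2, 1, 1)
        loss, n_conf = pseudo_label_loss(probs, probs, tau1=0.9)
        assert float(loss) == pytest.approx(-math.log(0.95), abs=1e-12)
        assert n_conf == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        student = random_probs(rng, 2, 3, 8, 8)
        ref = random_probs(rng, 2, 3, 8, 8)
        loss, n_conf = pseudo_label_loss(student, ref, tau1=0.45)
        o_loss, o_n = oracle_pseudo_loss(student, ref, 0.45)
        assert n_conf == o_n
        assert float(loss) == pytest.approx(o_loss, abs=1e-9)

    def test_unconfident_padding_decreases_loss(self, rng):
        """Enlarging the map with below-threshold pixels only grows the
        normaliser, so the loss strictly decreases."""
        student = random_probs(rng, 1, 2, 4, 4)
        ref = random_probs(rng, 1, 2, 4, 4)
        base, n0 = pseudo_label_loss(student, ref, tau1=0.55)
        pad_s = np.full((1, 2, 4, 4), 0.5)
        student2 = np.concatenate([student, pad_s], axis=2)
        ref2 = np.concatenate([ref, pad_s], axis=2)
        padded, n1 = pseudo_label_loss(student2, ref2, tau1=0.55)
        assert n1 == n0
        assert float(padded) < float(base)

    def test_reference_carries_no_gradient(self, rng):
        """Perturbing the reference map changes the loss value but the
        gradient flows only through the student probabilities."""
        student = Tensor(random_probs(rng, 1, 2, 4, 4), requires_grad=True)
        ref = random_probs(rng, 1, 2, 4, 4)
        loss, _ = pseudo_label_loss(student, ref, tau1=0.4)
        loss.backward()
        assert student.grad is not None and np.isfinite(student.grad).all()


class TestPerturbFeatures:
    def test_zero_prob_is_identity(self, rng):
        x = rng.standard_normal((4, 5))
        out = perturb_features(x, 0.0, rng)
        assert np.array_equal(out, x)

    def test_full_prob_residuals_standard_normal(self):
        rng = np.random.default_rng(0)
        x = np.zeros(100_000)
        res = perturb_features(x, 1.0, rng)
        assert abs(res.mean()) < 3 / math.sqrt(res.size)
        assert abs(res.var() - 1.0) < 3 * math.sqrt(2 / res.size)

    def test_unselected_elements_bit_identical(self, rng):
        x = rng.standard_normal(10_000)
        out = perturb_features(x, 0.3, np.random.default_rng(7))
        unchanged = out == x
        assert 0.5 < unchanged.mean() < 0.9  # ~70% untouched
        assert np.array_equal(out[unchanged], x[unchanged])


class TestConsistencyLoss:
    def _head(self, rng):
        return Conv2d(3, 2, 1, rng=rng)

    def test_no_perturbation_zero_both_modes(self, rng):
        head = self._head(rng)
        feats = Tensor(rng.standard_normal((2, 3, 4, 4)).astype(np.float32))
        for mode in ("soft", "hard"):
            val = consistency_loss(head, feats, 0.0, rng, mode=mode)
            assert float(val) == 0.0

    def test_soft_matches_scalar_oracle(self, rng):
        head = self._head(rng)
        feats = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        loss = consistency_loss(head, Tensor(feats), 0.8,
                                np.random.default_rng(3), mode="soft")
        # replay the same draws to rebuild the perturbed features
        rng2 = np.random.default_rng(3)
        mask = rng2.random(feats.shape) < 0.8
        pert = feats + (rng2.standard_normal(feats.shape) * mask).astype(np.float32)

        def softmax(a):
            e = np.exp(a - a.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        p0 = softmax(head(Tensor(feats)).data)
        p1 = softmax(head(Tensor(pert)).data)
        assert float(loss) == pytest.approx(np.mean((p0 - p1) ** 2), rel=1e-5)

    def test_hard_mode_returns_plain_float(self, rng):
        head = self._head(rng)
        feats = Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
        val = consistency_loss(head, feats, 0.5, rng, mode="hard")
        assert isinstance(val, float)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            consistency_loss(lambda x: x, Tensor(np.zeros((1, 1, 2, 2))),
                             0.1, rng, mode="argmax")


class TestReconstructionLoss:
    def test_identity_reconstruction_zero(self, rng):
        img = rng.standard_normal((2, 1, 4, 4))
        assert float(reconstruction_loss(Tensor(img), img)) == 0.0

    def test_constant_offset_two_gives_mse_four(self, rng):
        img = rng.standard_normal((2, 1, 4, 4))
        assert float(reconstruction_loss(Tensor(img + 2.0), img)) == pytest.approx(4.0)

    def test_standard_normal_kl_is_zero(self, rng):
        img = rng.standard_normal((2, 1, 4, 4))
        mu = Tensor(np.zeros((2, 8)))
        log_var = Tensor(np.zeros((2, 8)))
        with_kl = reconstruction_loss(Tensor(img), img, mu, log_var, kl_weight=1.0)
        assert float(with_kl) == 0.0


class TestRampup:
    def test_closed_form_points(self):
        assert rampup_weight(0, 100) == pytest.approx(math.exp(-5.0), abs=1e-12)
        assert rampup_weight(50, 100) == pytest.approx(math.exp(-1.25), abs=1e-12)
        assert rampup_weight(100, 100) == 1.0
        assert rampup_weight(250, 100) == 1.0

    def test_monotone_and_bounded(self):
        grid = [rampup_weight(t, 1000) for t in range(0, 2000, 2)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))
        assert math.exp(-5.0) <= grid[0] and grid[-1] <= 1.0

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            rampup_weight(1, 0)


class TestTotalLoss:
    def test_composition_arithmetic(self):
        cfg = LossConfig(rampup_len=100, w_pseudo=2.0, w_consistency=0.5,
                         w_reconstruction=0.25)
        comps = {"supervised": Tensor(1.0), "pseudo": Tensor(0.4),
                 "consistency": Tensor(0.2), "reconstruction": Tensor(0.8)}
        total, report = total_loss(comps, cfg, t=100)
        expected = 1.0 + 1.0 * (2.0 * 0.4 + 0.5 * 0.2 + 0.25 * 0.8)
        assert float(total) == pytest.approx(expected, abs=1e-12)
        assert report.delta == 1.0

    def test_rampup_suppresses_unsupervised_at_start(self):
        cfg = LossConfig(rampup_len=100)
        comps = {"supervised": Tensor(1.0), "pseudo": Tensor(100.0)}
        total, report = total_loss(comps, cfg, t=0)
        assert float(total) == pytest.approx(1.0 + math.exp(-5.0) * 100.0, rel=1e-9)

    def test_missing_branches_contribute_zero(self):
        cfg = LossConfig(rampup_len=10)
        total, report = total_loss({"supervised": Tensor(0.7)}, cfg, t=10)
        assert float(total) == pytest.approx(0.7)
        assert report.lu == report.lc == report.lrec == 0.0


class TestLossConfig:
    @pytest.mark.parametrize("kwargs", [
        {"tau1": 0.0}, {"tau1": 1.5}, {"perturb_prob": -0.1},
        {"rampup_len": 0}, {"w_pseudo": -1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LossConfig(**kwargs)
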