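"""Losses, training loop mechanics, evaluation protocol, entropy analytics."""

import math

import numpy as np
import pytest

from icseg.autodiff import Tensor
from icseg.datamodel import BinaryMask, EvalReport, dice_coefficient
from icseg.decoder import ProbabilityMap, SegmentationModel, binarize
from icseg.encoder import ModelConfig
from icseg.engine import (
    LossConfig,
    TrainConfig,
    cross_entropy_loss,
    dice_loss,
    evaluate,
    finetune_config,
    fit,
    mean_entropy,
    multi_position_loss,
    pixel_entropy,
)

CFG = LossConfig()


class TestCrossEntropy:
    def test_half_probability_gives_ln2(self):
        p = np.full((8, 8), 0.5)
        y = BinaryMask(np.random.default_rng(0).integers(0, 2, (8, 8)))
        assert float(cross_entropy_loss(p, y, CFG).data) == pytest.approx(math.log(2), abs=1e-9)

    def test_perfect_prediction_is_near_zero(self):
        y = np.zeros((4, 4), np.uint8)
        y[1:3, 1:3] = 1
        loss = float(cross_entropy_loss(y.astype(np.float64), BinaryMask(y), CFG).data)
        assert 0 <= loss <= -math.log(1 - CFG.ce_clamp) + 1e-12

    def test_single_pixel_closed_form(self):
        loss = float(cross_entropy_loss(np.array([[0.9]]), BinaryMask(np.array([[1]])), CFG).data)
        assert loss == pytest.approx(-math.log(0.9), abs=1e-9)  # 0.10536

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((2, 2)), BinaryMask(np.zeros((3, 3), int)), CFG)


class TestDiceLoss:
    def test_perfect_one_hot_is_zero(self):
        y = np.zeros((5, 5), np.uint8)
        y[:2, :5] = 1  # 10 foreground pixels
        assert float(dice_loss(y.astype(float), BinaryMask(y), CFG).data) == pytest.approx(0.0, abs=1e-9)

    def test_doubly_empty_is_zero(self):
        z = np.zeros((4, 4))
        assert float(dice_loss(z, BinaryMask(z.astype(np.uint8)), CFG).data) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_prediction_against_ten_ones(self):
        y = np.zeros((5, 5), np.uint8)
        y[0, :5] = 1
        y[1, :5] = 1
        loss = float(dice_loss(np.zeros((5, 5)), BinaryMask(y), CFG).data)
        assert loss == pytest.approx(1 - CFG.dice_epsilon / (10 + CFG.dice_epsilon), rel=1e-9)

    def test_disjoint_near_one(self):
        y = np.zeros((4, 4), np.uint8)
        y[0] = 1
        p = np.zeros((4, 4))
        p[2] = 1.0
        assert float(dice_loss(p, BinaryMask(y), CFG).data) > 0.999


class TestLossGradients:
    def test_finite_difference_on_four_pixel_toy(self):
        """Autodiff gradient of CE+Dice matches central differences at 1e-4 relative."""
        y = BinaryMask(np.array([[1, 0], [0, 1]]))
        p0 = np.array([[0.7, 0.2], [0.4, 0.6]])

        def f(arr):
            t = Tensor(arr)
            return float((cross_entropy_loss(t, y, CFG) + dice_loss(t, y, CFG)).data)

        t = Tensor(p0.copy(), requires_grad=True)
        loss = cross_entropy_loss(t, y, CFG) + dice_loss(t, y, CFG)
        loss.backward()
        eps = 1e-7
        for idx in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            pp = p0.copy()
            pp[idx] += eps
            pm = p0.copy()
            pm[idx] -= eps
            num = (f(pp) - f(pm)) / (2 * eps)
            assert abs(num - t.grad[idx]) <= 1e-4 * max(abs(num), 1.0)


class TestMultiPosition:
    def test_single_position_is_plain_loss(self):
        y = BinaryMask(np.array([[1, 0], [1, 1]]))
        p = np.array([[0.8, 0.1], [0.9, 0.7]])
        single = float(multi_position_loss([p], [y], CFG).data)
        direct = float((cross_entropy_loss(p, y, CFG) + dice_loss(p, y, CFG)).data)
        assert single == pytest.approx(direct, rel=1e-12)

    def test_mean_of_constructed_losses(self):
        """Weights chosen so per-position combined losses are known; mean checks out."""
        y1 = BinaryMask(np.ones((2, 2), np.uint8))
        y2 = BinaryMask(np.zeros((2, 2), np.uint8))
        p1 = np.full((2, 2), 0.9)
        p2 = np.full((2, 2), 0.2)
        l1 = float((cross_entropy_loss(p1, y1, CFG) + dice_loss(p1, y1, CFG)).data)
        l2 = float((cross_entropy_loss(p2, y2, CFG) + dice_loss(p2, y2, CFG)).data)
        total = float(multi_position_loss([p1, p2], [y1, y2], CFG).data)
        assert total == pytest.approx((l1 + l2) / 2, rel=1e-9)

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            multi_position_loss([np.zeros((2, 2))], [], CFG)


class TestFit:
    def test_lr_zero_equivalent_noop(self, tiny_dataset):
        """With an (effectively) zero learning rate parameters do not move."""
        model = SegmentationModel(ModelConfig.tiny(), seed=5)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(lr=1e-30, epochs=1, steps_per_epoch=2, n_pairs=2,
                          batch_episodes=1, seed=1, augment=False)
        fit(model, tiny_dataset, cfg)
        after = model.state_dict()
        assert all(np.allclose(before[k], after[k], atol=1e-12) for k in before)

    def test_same_seed_bit_identical_loss_series(self, tiny_dataset):
        histories = []
        for _ in range(2):
            model = SegmentationModel(ModelConfig.tiny(), seed=5)
            cfg = TrainConfig(lr=1e-3, epochs=1, steps_per_epoch=3, n_pairs=2,
                              batch_episodes=1, seed=9)
            histories.append(fit(model, tiny_dataset, cfg)["loss"])
        assert histories[0] == histories[1]

    def test_loss_log_written(self, tiny_dataset, tmp_path):
        model = SegmentationModel(ModelConfig.tiny(), seed=5)
        cfg = TrainConfig(lr=1e-3, epochs=1, steps_per_epoch=2, n_pairs=2,
                          batch_episodes=1, seed=2)
        fit(model, tiny_dataset, cfg, log_path=tmp_path / "loss.csv")
        lines = (tmp_path / "loss.csv").read_text().strip().splitlines()
        assert lines[0] == "step,loss,lr" and len(lines) == 3

    def test_finetune_config_halves_lr(self):
        base = TrainConfig(lr=2e-4)
        ft = finetune_config(base, epochs=1)
        assert ft.lr == pytest.approx(1e-4) and ft.epochs == 1


class OracleModel:
    """Stand-in 'model' that returns the query's ground truth; exercised only
    through predict_query, so it can drive protocol tests without training."""

    def __init__(self, dataset):
        self.lookup = {}
        for c, samples in dataset.items():
            for img, msk in samples:
                self.lookup[(c, img.pixels.tobytes())] = msk.labels

    def predict_query(self, episode):
        labels = self.lookup[(episode.class_id, episode.query.pixels.tobytes())]
        return ProbabilityMap(labels.astype(np.float32))


class TestEvaluate:
    def test_oracle_model_scores_one(self, tiny_eval_dataset):
        report = evaluate(OracleModel(tiny_eval_dataset), tiny_eval_dataset,
                          k_prompts=2, n_repeats=2, seed=3)
        assert report.mean_dsc == 1.0
        assert all(v == 1.0 for v in report.per_class_dsc.values())

    def test_fixed_seed_is_reproducible(self, tiny_eval_dataset):
        model = SegmentationModel(ModelConfig.tiny(), seed=7)
        r1 = evaluate(model, tiny_eval_dataset, k_prompts=2, n_repeats=2, seed=5,
                      max_queries_per_class=2)
        r2 = evaluate(model, tiny_eval_dataset, k_prompts=2, n_repeats=2, seed=5,
                      max_queries_per_class=2)
        assert r1.per_class_dsc == r2.per_class_dsc and r1.mean_dsc == r2.mean_dsc

    def test_mean_is_arithmetic_over_classes(self):
        report = EvalReport(per_class_dsc={1: 0.6, 2: 0.8}, mean_dsc=0.7, n_repeats=5)
        assert report.mean_dsc == pytest.approx(np.mean(list(report.per_class_dsc.values())))

    def test_insufficient_support_errors(self, tiny_eval_dataset):
        model = SegmentationModel(ModelConfig.tiny(), seed=7)
        with pytest.raises(ValueError):
            evaluate(model, tiny_eval_dataset, k_prompts=99, n_repeats=1, seed=1)


class TestEntropy:
    def test_closed_forms(self):
        eps = 1e-8
        h_half = pixel_entropy(ProbabilityMap(np.full((2, 2), 0.5, np.float32))).values
        assert np.allclose(h_half, math.log(2), atol=2 * eps)
        h_hard = pixel_entropy(ProbabilityMap(np.array([[0.0, 1.0]], np.float32))).values
        assert (np.abs(h_hard) <= 2 * eps).all()
        h_09 = pixel_entropy(ProbabilityMap(np.full((1, 1), 0.9, np.float32))).values
        expected = -(0.9 * math.log(0.9 + eps) + 0.1 * math.log(0.1 + eps))
        assert h_09[0, 0] == pytest.approx(expected, abs=1e-7)
        assert h_09[0, 0] == pytest.approx(0.32508, abs=1e-4)

    def test_symmetric_and_unimodal(self):
        ps = np.linspace(0.0, 1.0, 101, dtype=np.float32)
        h = pixel_entropy(ProbabilityMap(ps.reshape(1, -1))).values.ravel()
        assert np.allclose(h, h[::-1], atol=1e-9)  # symmetry under p -> 1-p
        assert (np.diff(h[:51]) > -1e-12).all()  # increasing toward 0.5
        assert (np.diff(h[50:]) < 1e-12).all()  # decreasing after 0.5

    def test_mean_entropy_limits(self, tiny_eval_dataset):
        class Half:
            def predict_query(self, episode):
                size = episode.query.pixels.shape[0]
                return ProbabilityMap(np.full((size, size), 0.5, np.float32))

        val = mean_entropy(Half(), tiny_eval_dataset, k_prompts=1, seed=1,
                           max_queries_per_class=1)
        assert val == pytest.approx(math.log(2), abs=1e-6)
        oracle = OracleModel(tiny_eval_dataset)
        val0 = mean_entropy(oracle, tiny_eval_dataset, k_prompts=1, seed=1,
                            max_queries_per_class=1)
        assert abs(val0) < 1e-6
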