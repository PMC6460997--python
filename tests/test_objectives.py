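"""Losses and metrics against independent scalar-loop references."""

import math

import numpy as np
import pytest

from ndnseg.objectives import (
    CLIP_FLOOR,
    ConfusionCounts,
    ProbabilityField,
    confusion_counts,
    cross_entropy,
    dice_loss,
    dice_score,
    evaluate_case,
    focal_loss,
    loss_and_logit_grad,
    one_hot,
    weighted_cross_entropy,
)
from ndnseg.volio import LabelVolume

# ---------------------------------------------------------------------------
# independent scalar-loop references


def _loop_cross_entropy(q, p, weights=None):
    total = 0.0
    q2, p2 = q.reshape(-1, q.shape[-1]), p.reshape(-1, p.shape[-1])
    for v in range(len(q2)):
        for k in range(q2.shape[1]):
            w = 1.0 if weights is None else weights[k]
            total -= w * p2[v, k] * math.log(min(max(q2[v, k], CLIP_FLOOR), 1.0))
    return total / len(q2)


def _loop_focal(q, p, gamma):
    num, den = 0.0, 0.0
    q2, p2 = q.reshape(-1, q.shape[-1]), p.reshape(-1, p.shape[-1])
    for v in range(len(q2)):
        for k in range(q2.shape[1]):
            qc = min(max(q2[v, k], CLIP_FLOOR), 1.0)
            num -= p2[v, k] * (1 - q2[v, k]) ** gamma * math.log(qc)
            den += p2[v, k]
    return num / den


def _loop_dice(q, p, eps=1e-5, include_background=True):
    overlap = sp = sq = 0.0
    q2, p2 = q.reshape(-1, q.shape[-1]), p.reshape(-1, p.shape[-1])
    start = 0 if include_background else 1
    for v in range(len(q2)):
        for k in range(start, q2.shape[1]):
            overlap += p2[v, k] * q2[v, k]
            sp += p2[v, k]
            sq += q2[v, k]
    return 1.0 - 2.0 * overlap / (sp + sq + eps)


def _random_field(rng, n=1000, k=4):
    logits = rng.normal(size=(n, k))
    q = np.exp(logits) / np.exp(logits).sum(axis=-1, keepdims=True)
    p = one_hot(rng.integers(0, k, size=n), k)
    return ProbabilityField(q=q, p=p)


# ---------------------------------------------------------------------------


class TestConfusionAndDice:
    def test_enumerated_four_voxels(self):
        c = confusion_counts([1, 1, 1, 0], [1, 0, 1, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 0)

    def test_perfect_prediction(self, rng):
        mask = rng.random((4, 4, 4)) < 0.5
        c = confusion_counts(mask, mask)
        assert c.fp == 0 and c.fn == 0
        assert dice_score(mask, mask) == 1.0

    def test_counts_partition_grid(self, rng):
        a, b = rng.random((5, 5, 5)) < 0.5, rng.random((5, 5, 5)) < 0.5
        assert confusion_counts(a, b).total == 125

    def test_dice_hand_value(self):
        # TP=6, FP=2, FN=2 -> 12/16
        pred = np.array([1] * 8 + [0] * 2)
        true = np.array([1] * 6 + [0] * 2 + [1] * 2)
        assert dice_score(pred, true) == pytest.approx(0.75)

    def test_disjoint_masks_and_empty_convention(self):
        assert dice_score([1, 0], [0, 1]) == 0.0
        assert dice_score([0, 0], [0, 0]) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 2)))


class TestLossValues:
    def test_cross_entropy_single_voxel(self):
        q = np.array([[0.25, 0.25, 0.25, 0.25]])
        p = one_hot(np.array([2]), 4)
        field = ProbabilityField(q=q, p=p)
        assert cross_entropy(field) == pytest.approx(1.3863, abs=1e-4)

    def test_weighted_doubles_class_two(self):
        q = np.array([[0.25, 0.25, 0.25, 0.25]])
        p = one_hot(np.array([2]), 4)
        field = ProbabilityField(q=q, p=p)
        assert weighted_cross_entropy(field, (1, 1, 2, 1)) == pytest.approx(2.7726, abs=1e-4)

    def test_weighted_all_ones_reduces_to_plain(self, rng):
        field = _random_field(rng, n=100)
        assert weighted_cross_entropy(field, (1, 1, 1, 1)) == pytest.approx(
            cross_entropy(field), abs=1e-12
        )

    def test_perfect_prediction_near_zero(self):
        p = one_hot(np.array([0, 1, 2, 3]), 4)
        field = ProbabilityField(q=p.copy(), p=p)
        assert cross_entropy(field) == pytest.approx(0.0, abs=1e-12)
        assert dice_loss(field) == pytest.approx(0.0, abs=1e-4)
        assert focal_loss(field) == pytest.approx(0.0, abs=1e-12)

    def test_focal_single_voxel_hand_value(self):
        # q_true = 0.5, gamma 2: 0.25 * ln 2 = 0.1733
        q = np.array([[0.5, 0.5]])
        p = one_hot(np.array([0]), 2)
        field = ProbabilityField(q=q, p=p)
        assert focal_loss(field, gamma=2.0) == pytest.approx(0.1733, abs=1e-4)

    def test_focal_gamma_zero_is_cross_entropy(self, rng):
        field = _random_field(rng, n=200)
        assert focal_loss(field, gamma=0.0) == pytest.approx(cross_entropy(field), abs=1e-6)

    def test_dice_hand_value_uniform_half(self):
        # 4 voxels, 2 classes, q uniform 0.5: 1 - 2*2/(4+4) = 0.5
        p = one_hot(np.array([0, 0, 1, 1]), 2)
        q = np.full((4, 2), 0.5)
        field = ProbabilityField(q=q, p=p)
        assert dice_loss(field, mode="canonical") == pytest.approx(0.5, abs=1e-4)

    def test_dice_as_printed_scales_by_voxel_count(self, rng):
        field = _random_field(rng, n=50)
        canonical = dice_loss(field, mode="canonical")
        printed = dice_loss(field, mode="as_printed")
        assert printed == pytest.approx(1 - (1 - canonical) / 50, abs=1e-12)


class TestLoopOracles:
    def test_vectorized_matches_scalar_loops(self, rng):
        field = _random_field(rng, n=1000)
        q, p = field.q, field.p
        assert cross_entropy(field) == pytest.approx(_loop_cross_entropy(q, p), abs=1e-6)
        assert weighted_cross_entropy(field, (1, 1, 2, 1)) == pytest.approx(
            _loop_cross_entropy(q, p, (1, 1, 2, 1)), abs=1e-6
        )
        assert focal_loss(field, 2.0) == pytest.approx(_loop_focal(q, p, 2.0), abs=1e-6)
        assert dice_loss(field) == pytest.approx(_loop_dice(q, p), abs=1e-6)

    def test_many_small_random_fields(self, rng):
        for _ in range(100):
            field = _random_field(rng, n=20)
            assert cross_entropy(field) == pytest.approx(
                _loop_cross_entropy(field.q, field.p), abs=1e-6
            )
            assert dice_loss(field) == pytest.approx(_loop_dice(field.q, field.p), abs=1e-6)


class TestGradients:
    @pytest.mark.parametrize("kind", ["ce", "wce", "focal", "dice"])
    def test_logit_gradient_matches_finite_differences(self, kind, rng):
        logits = rng.normal(size=(30, 4))
        p = one_hot(rng.integers(0, 4, size=30), 4)
        _, grad = loss_and_logit_grad(logits, p, kind=kind, dice_include_background=True)
        eps = 1e-6
        for _ in range(8):
            i, k = rng.integers(30), rng.integers(4)
            logits[i, k] += eps
            lp, _ = loss_and_logit_grad(logits, p, kind=kind, dice_include_background=True)
            logits[i, k] -= 2 * eps
            lm, _ = loss_and_logit_grad(logits, p, kind=kind, dice_include_background=True)
            logits[i, k] += eps
            assert (lp - lm) / (2 * eps) == pytest.approx(grad[i, k], rel=1e-4, abs=1e-8)

    def test_foreground_only_dice_gradient(self, rng):
        logits = rng.normal(size=(30, 2))
        p = one_hot(rng.integers(0, 2, size=30), 2)
        _, grad = loss_and_logit_grad(logits, p, kind="dice", dice_include_background=False)
        eps = 1e-6
        for _ in range(6):
            i, k = rng.integers(30), rng.integers(2)
            logits[i, k] += eps
            lp, _ = loss_and_logit_grad(logits, p, kind="dice", dice_include_background=False)
            logits[i, k] -= 2 * eps
            lm, _ = loss_and_logit_grad(logits, p, kind="dice", dice_include_background=False)
            logits[i, k] += eps
            assert (lp - lm) / (2 * eps) == pytest.approx(grad[i, k], rel=1e-4, abs=1e-8)

    @pytest.mark.parametrize("kind", ["ce", "wce", "focal", "dice"])
    def test_losses_decrease_as_true_class_probability_rises(self, kind):
        # one voxel, one free logit for the true class
        losses = []
        for z in np.linspace(-2, 2, 9):
            logits = np.array([[z, 0.0]])
            p = one_hot(np.array([0]), 2)
            loss, _ = loss_and_logit_grad(logits, p, kind=kind, dice_include_background=True)
            losses.append(loss)
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_losses_nonnegative_on_random_fields(self, rng):
        for _ in range(20):
            field = _random_field(rng, n=40)
            assert cross_entropy(field) >= 0
            assert weighted_cross_entropy(field) >= 0
            assert focal_loss(field) >= 0
            assert dice_loss(field) >= 0


class TestEvaluateCase:
    def test_identity_gives_perfect_scores(self, rng):
        lab = LabelVolume(rng.integers(0, 4, size=(6, 6, 4)))
        assert evaluate_case(lab, LabelVolume(lab.labels.copy())) == {1: 1.0, 2: 1.0, 3: 1.0}

    def test_both_empty_class_scores_one(self, rng):
        grid = rng.integers(0, 3, size=(6, 6, 4))  # no class 3
        scores = evaluate_case(LabelVolume(grid), LabelVolume(grid.copy()))
        assert scores[3] == 1.0

    def test_erosion_matches_confusion_count_oracle(self, small_phantom):
        from scipy import ndimage

        _, labels = small_phantom
        eroded = labels.labels.copy()
        mask1 = labels.labels == 1
        eroded[mask1 & ~ndimage.binary_erosion(mask1)] = 0
        scores = evaluate_case(LabelVolume(eroded), labels)
        c = confusion_counts(eroded == 1, labels.labels == 1)
        assert scores[1] == pytest.approx(2 * c.tp / (c.fp + 2 * c.tp + c.fn))


class TestFieldValidation:
    def test_rejects_non_onehot_truth(self):
        q = np.full((2, 2), 0.5)
        with pytest.raises(ValueError):
            ProbabilityField(q=q, p=np.full((2, 2), 0.5))

    def test_rejects_unnormalized_probabilities(self):
        p = one_hot(np.array([0, 1]), 2)
        with pytest.raises(ValueError):
            ProbabilityField(q=np.array([[0.9, 0.6], [0.5, 0.5]]), p=p)
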