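"""Loss and metric semantics, checked against naive loop implementations."""
import math

import numpy as np
import pytest

from frugalseg.objective import (LossConfig, PFRInput, batch_loss_and_grad,
                                 cal_class, cal_loss, combined_loss,
                                 dice_loss, dsc_class, evaluate_dataset,
                                 iou_class, loss_and_grad, pfr, sigmoid)

from conftest import random_sample

EPS = 1e-7


# -- naive reference implementations (plain triple loops) -------------------

def loop_dsc(gt, pred, c, eps=EPS):
    num = sg = sp = 0.0
    for u in range(gt.shape[0]):
        for v in range(gt.shape[1]):
            num += gt[u, v, c] * pred[u, v, c]
            sg += gt[u, v, c]
            sp += pred[u, v, c]
    return (2.0 * num + eps) / (sg + sp + eps)


def loop_dice_loss(gt, pred, m, eps=EPS):
    acc = 0.0
    for c in range(gt.shape[2]):
        acc += m[c] * (1.0 - loop_dsc(gt, pred, c, eps))
    return acc / sum(m)


def loop_cal(gt, pred, m, c, background_index=None):
    total = 0.0
    for u in range(gt.shape[0]):
        for v in range(gt.shape[1]):
            inner = 0.0
            for z in range(gt.shape[2]):
                if z == c or z == background_index:
                    continue
                inner += (1.0 / (1.0 + math.exp(-pred[u, v, z]))) * (1 - m[z])
            total += gt[u, v, c] * inner
    return total


def loop_cal_loss(gt, pred, m, background_index=None):
    acc = 0.0
    for c in range(gt.shape[2]):
        if c == background_index:
            continue
        acc += m[c] * loop_cal(gt, pred, m, c, background_index)
    return acc


def loop_combined(gt, pred, m, alpha, background_index=None):
    return ((1 - alpha) * loop_dice_loss(gt, pred, m)
            + alpha * loop_cal_loss(gt, pred, m, background_index))


# -- hand-derived examples --------------------------------------------------

def test_dsc_perfect_and_empty_channels():
    gt = np.zeros((3, 3, 2))
    gt[0, 0, 0] = gt[1, 2, 0] = 1
    pred = gt.astype(float)
    assert dsc_class(gt, pred, 0) == pytest.approx(1.0)
    # both channels empty: forced to 1 by the eps smoothing
    assert dsc_class(gt, pred, 1) == pytest.approx(1.0)


def test_dsc_hand_example_2x2():
    # overlap 1, areas 2 and 1 -> (2 + eps) / (3 + eps)
    gt = np.zeros((2, 2, 1))
    gt[0, 0, 0] = gt[0, 1, 0] = 1
    pred = np.zeros((2, 2, 1))
    pred[0, 0, 0] = 1
    assert dsc_class(gt, pred, 0) == pytest.approx(2 / 3, abs=1e-6)


def test_dice_loss_single_labeled_class():
    gt = np.zeros((2, 2, 2))
    gt[0, 0, 0] = gt[0, 1, 0] = 1
    pred = np.zeros((2, 2, 2))
    pred[0, 0, 0] = 1
    m = [1, 0]
    assert dice_loss(gt, pred, m) == pytest.approx(1 - 2 / 3, abs=1e-6)


def test_dice_loss_ignores_appended_unlabeled_channels():
    rng = np.random.default_rng(1)
    gt, pred, m = random_sample(rng, 5, 4, 3)
    base = dice_loss(gt, pred, m)
    gt2 = np.concatenate([gt, np.zeros((5, 4, 2))], axis=-1)
    pred2 = np.concatenate([pred, rng.random((5, 4, 2))], axis=-1)
    m2 = np.concatenate([m, [0, 0]])
    assert dice_loss(gt2, pred2, m2) == pytest.approx(base, abs=1e-9)


def test_dice_loss_rejects_fully_unlabeled_sample():
    gt = np.zeros((2, 2, 2))
    with pytest.raises(ValueError, match="no labeled class"):
        dice_loss(gt, gt, [0, 0])


def test_cal_hand_example_sigmoid():
    # one labeled pixel of class 0; unlabeled channel predicts 0.9
    gt = np.zeros((1, 1, 2))
    gt[0, 0, 0] = 1
    pred = np.zeros((1, 1, 2))
    pred[0, 0, 1] = 0.9
    m = [1, 0]
    expected = 1.0 / (1.0 + math.exp(-0.9))
    assert cal_class(gt, pred, m, 0) == pytest.approx(expected, abs=1e-6)
    assert expected == pytest.approx(0.7109, abs=5e-5)
    assert cal_loss(gt, pred, m) == pytest.approx(expected, abs=1e-6)
    # no labeled ground truth at the pixel -> no penalty
    gt[0, 0, 0] = 0
    assert cal_class(gt, pred, m, 0) == 0.0


def test_cal_vanishes_when_fully_labeled():
    rng = np.random.default_rng(2)
    gt, pred, _ = random_sample(rng, 6, 6, 4)
    m = np.ones(4)
    assert cal_loss(gt, pred, m) == 0.0
    for c in range(4):
        assert cal_class(gt, pred, m, c) == 0.0


def test_cal_invariant_to_permuting_unlabeled_channels():
    rng = np.random.default_rng(3)
    gt, pred, _ = random_sample(rng, 4, 4, 4)
    m = np.array([1.0, 0.0, 0.0, 1.0])
    base = cal_loss(gt, pred, m)
    # swap the two unlabeled channels (1 and 2) everywhere
    perm = [0, 2, 1, 3]
    assert cal_loss(gt[..., perm], pred[..., perm], m[perm]) == \
        pytest.approx(base, abs=1e-9)


def test_cal_masking_soundness():
    """Changing labeled channels (z != c) at pixels outside class c's mask
    never changes cal_class(c)."""
    rng = np.random.default_rng(4)
    gt, pred, _ = random_sample(rng, 5, 5, 3)
    m = np.array([1.0, 1.0, 0.0])
    base = cal_class(gt, pred, m, 0)
    mod = pred.copy()
    outside = gt[..., 0] == 0
    mod[outside, 1] = rng.random(outside.sum())
    assert cal_class(gt, mod, m, 0) == pytest.approx(base, abs=1e-9)


def test_combined_loss_weighting():
    rng = np.random.default_rng(5)
    gt, pred, m = random_sample(rng, 4, 4, 3)
    for alpha in (0.0, 0.4, 0.99):
        cfg = LossConfig(alpha=alpha)
        expected = ((1 - alpha) * dice_loss(gt, pred, m, cfg)
                    + alpha * cal_loss(gt, pred, m, cfg))
        assert combined_loss(gt, pred, m, cfg) == pytest.approx(expected)
    # alpha = 0 reduces exactly to the Dice loss
    cfg0 = LossConfig(alpha=0.0)
    assert combined_loss(gt, pred, m, cfg0) == \
        pytest.approx(dice_loss(gt, pred, m, cfg0))


def test_alpha_one_rejected():
    with pytest.raises(ValueError, match="cannot operate on its own"):
        LossConfig(alpha=1.0)


def test_perfect_fully_labeled_prediction_gives_zero_loss():
    gt = np.zeros((4, 4, 3))
    gt[:2, :, 0] = 1
    gt[2:, :2, 1] = 1
    gt[2:, 2:, 2] = 1
    m = np.ones(3)
    for alpha in (0.0, 0.4, 0.8):
        cfg = LossConfig(alpha=alpha)
        assert combined_loss(gt, gt.astype(float), m, cfg) == \
            pytest.approx(0.0, abs=1e-6)


def test_dsc_symmetry_on_binary_inputs():
    rng = np.random.default_rng(6)
    a = (rng.random((6, 5, 2)) > 0.5).astype(float)
    b = (rng.random((6, 5, 2)) > 0.5).astype(float)
    for c in range(2):
        assert dsc_class(a, b, c) == pytest.approx(dsc_class(b, a, c))


def test_shape_and_index_errors():
    gt = np.zeros((3, 3, 2))
    with pytest.raises(ValueError, match="shape mismatch"):
        dsc_class(gt, np.zeros((3, 4, 2)), 0)
    with pytest.raises(IndexError):
        dsc_class(gt, gt, 5)


# -- oracle equivalence on random inputs ------------------------------------

@pytest.mark.parametrize("background_index", [None, -1])
def test_vectorized_losses_match_loop_oracle(background_index):
    """Vectorized Dice/asymmetric/combined losses agree with naive triple
    loops within 1e-6 on >= 100 random small inputs."""
    rng = np.random.default_rng(42)
    for trial in range(110):
        h, w = rng.integers(1, 9, size=2)
        C = int(rng.integers(2, 5))
        bg = None if background_index is None else C - 1
        gt, pred, m = random_sample(rng, h, w, C)
        alpha = float(rng.uniform(0, 0.99))
        cfg = LossConfig(alpha=alpha, background_index=bg)
        assert dice_loss(gt, pred, m, cfg) == \
            pytest.approx(loop_dice_loss(gt, pred, m), abs=1e-6)
        assert cal_loss(gt, pred, m, cfg) == \
            pytest.approx(loop_cal_loss(gt, pred, m, bg), abs=1e-6)
        assert combined_loss(gt, pred, m, cfg) == \
            pytest.approx(loop_combined(gt, pred, m, alpha, bg), abs=1e-6)
        for c in range(C):
            assert dsc_class(gt, pred, c) == \
                pytest.approx(loop_dsc(gt, pred, c), abs=1e-6)


def test_gradient_matches_finite_differences():
    """Analytic d(loss)/d(prediction) agrees with central differences,
    including the zero gradient on unlabeled channels at alpha = 0."""
    rng = np.random.default_rng(7)
    gt, pred, m = random_sample(rng, 3, 3, 3)
    m = np.array([1.0, 0.0, 1.0])
    for alpha in (0.0, 0.5):
        cfg = LossConfig(alpha=alpha, background_index=2)
        _, grad = loss_and_grad(gt, pred, m, cfg)
        eps = 1e-6
        for u in range(3):
            for v in range(3):
                for c in range(3):
                    p = pred.copy()
                    p[u, v, c] += eps
                    up = combined_loss(gt, p, m, cfg)
                    p[u, v, c] -= 2 * eps
                    dn = combined_loss(gt, p, m, cfg)
                    num = (up - dn) / (2 * eps)
                    assert grad[u, v, c] == pytest.approx(num, abs=1e-4)


def test_batch_loss_averages_per_sample_losses():
    rng = np.random.default_rng(8)
    cfg = LossConfig(alpha=0.3, background_index=2)
    samples = [random_sample(rng, 4, 4, 3) for _ in range(3)]
    gt = np.stack([s[0] for s in samples])
    pred = np.stack([s[1] for s in samples])
    m = np.stack([s[2] for s in samples])
    (L, _, _), _ = batch_loss_and_grad(gt, pred, m, cfg)
    per_sample = [combined_loss(*s, cfg) for s in samples]
    assert L == pytest.approx(np.mean(per_sample), abs=1e-5)


# -- IoU / PFR / evaluation -------------------------------------------------

def test_iou_cases():
    a = np.zeros((4, 4, 1))
    b = np.zeros((4, 4, 1))
    a[:2, :2, 0] = 1        # area 4
    b[1:3, :2, 0] = 1       # area 4, overlap 2
    assert iou_class(a, b, 0) == pytest.approx(2 / 6)
    assert iou_class(a, a, 0) == 1.0
    c = np.zeros((4, 4, 1))
    c[3, 3, 0] = 1
    assert iou_class(a, c, 0) == 0.0
    empty = np.zeros((4, 4, 1))
    assert iou_class(empty, empty, 0) == 1.0


def test_pfr_formula_and_domain():
    assert pfr(0.9, 110, 10) == pytest.approx(0.009)
    assert pfr(PFRInput(0.8, 100)) == pytest.approx(0.008)
    # halving the available labels doubles the ratio
    assert pfr(0.6, 40, 20) == pytest.approx(2 * pfr(0.6, 40, 0))
    with pytest.raises(ValueError):
        pfr(0.5, 10, 10)


def test_evaluate_dataset_perfect_prediction():
    gt = np.zeros((4, 4, 3))
    gt[:2, :, 0] = 1
    gt[2:, :, 1] = 1
    gt[..., 2] = 1 - gt[..., :2].max(-1)
    report = evaluate_dataset([(gt, gt.astype(float))], [0, 1],
                              available_labels=10)
    assert report["mdsc"] == pytest.approx(1.0)
    assert report["miou"] == pytest.approx(1.0)
    assert report["mpfr_dsc"] == pytest.approx(0.1)
    per = report["per_class_dsc"]
    assert report["mdsc"] == pytest.approx(np.mean([per[0], per[1]]))


def test_evaluate_dataset_rejects_empty():
    with pytest.raises(ValueError):
        evaluate_dataset([], [0])
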