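"""Losses and metrics for multi-class segmentation with heterogeneous labels.

A sample is an RGB image ``x`` with a ground-truth tensor ``y`` of shape
``(h, w, C)`` (one binary channel per class, background included as its own
channel) and a binary mask vector ``m`` of length ``C`` flagging which
classes actually carry a ground-truth mask for this sample.  Heterogeneous
(partially labeled) datasets are those where ``m`` varies between samples.

Two complementary objectives are combined:

* the mask-weighted soft Dice loss ``L_DSC`` — the mean of ``1 - DSC`` over
  the *labeled* channels only, so missing masks contribute neither signal
  nor noise; and
* the class-asymmetric loss ``L_CAL`` — for every labeled class ``c`` and
  every pixel known to belong to ``c``, a penalty on the (activated)
  predicted mass in the *unlabeled* channels, exploiting that segmentation
  classes are mutually exclusive: a pixel with a ground truth cannot belong
  to any unlabeled class.

The combined objective is ``L = (1 - alpha) * L_DSC + alpha * L_CAL`` with
``alpha in [0, 1)``; ``alpha = 1`` is invalid because ``L_CAL`` only
constrains unlabeled channels and cannot drive training alone.

A naive background class (complement of the labeled foreground) cannot be
distinguished from "unlabeled", so the background channel is excluded from
``L_CAL`` entirely (both as the labeled class ``c`` and as an unlabeled
channel ``z``) via ``LossConfig.background_index``.

The Performance Frugality Ratio ``PFR(M) = M / n`` relates an evaluation
statistic ``M`` (e.g. DSC or IoU) to the number of available labels
``n = S - P``, rewarding methods that achieve performance with fewer labels.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LossConfig",
    "PFRInput",
    "sigmoid",
    "dsc_class",
    "dice_loss",
    "cal_class",
    "cal_loss",
    "combined_loss",
    "loss_components",
    "loss_and_grad",
    "batch_loss_and_grad",
    "iou_class",
    "pfr",
    "evaluate_dataset",
]

EPSILON = 1e-7


def sigmoid(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                    np.exp(np.clip(x, -500, 0)) /
                    (1.0 + np.exp(np.clip(x, -500, 0))))


def _sigmoid_grad(x):
    s = sigmoid(x)
    return s * (1.0 - s)


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "sigmoid": (sigmoid, _sigmoid_grad),
    "identity": (lambda x: np.asarray(x, dtype=float), np.ones_like),
}


@dataclass
class LossConfig:
    """Configuration of the combined objective.

    Parameters
    ----------
    alpha
        Weight of the class-asymmetric term, in ``[0, 1)``.
    epsilon
        Additive smoothing in numerator and denominator of the Dice
        coefficient; makes empty-vs-empty DSC equal 1 and avoids 0/0.
    activation
        Monotone map applied to predicted values inside the asymmetric
        term ("sigmoid" or "identity").  Note the sigmoid maps 0 to 0.5,
        so even zero predicted mass in an unlabeled channel contributes a
        constant offset per labeled pixel; kept as the reference semantics.
    background_index
        Channel excluded from the asymmetric term, or None.
    normalize_cal
        If True, divide the asymmetric term by the pixel count ``h*w`` so
        its scale is comparable to the Dice term.  Off by default: the
        reference definition is an unnormalised pixel sum.
    """

    alpha: float = 0.0
    epsilon: float = EPSILON
    activation: str = "sigmoid"
    background_index: int | None = None
    normalize_cal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(
                f"alpha must be in [0, 1); got {self.alpha}. alpha = 1 is "
                "invalid: the class-asymmetric loss only constrains "
                "unlabeled channels and cannot operate on its own.")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def f(self) -> Callable:
        return _ACTIVATIONS[self.activation][0]

    @property
    def f_grad(self) -> Callable:
        return _ACTIVATIONS[self.activation][1]


@dataclass
class PFRInput:
    """Inputs of the Performance Frugality Ratio.

    ``statistic`` is an evaluation statistic such as a (m)DSC or (m)IoU
    value; ``total_samples`` is the number of sample-label pairs ``S`` and
    ``dropped_labels`` the number ``P`` of dropped ones, so the number of
    available labels is ``n = S - P``.
    """

    statistic: float
    total_samples: int
    dropped_labels: int = 0

    @property
    def available_labels(self) -> int:
        return self.total_samples - self.dropped_labels


def _check_pair(gt: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if gt.ndim != 3 or pred.ndim != 3:
        raise ValueError("ground truth and prediction must be (h, w, C)")
    if gt.shape != pred.shape:
        raise ValueError(
            f"shape mismatch: ground truth {gt.shape} vs prediction {pred.shape}")
    return gt, pred


def _check_class(c: int, C: int) -> None:
    if not 0 <= c < C:
        raise IndexError(f"class index {c} out of range for C={C}")


def dsc_class(gt: np.ndarray, pred: np.ndarray, c: int,
              epsilon: float = EPSILON) -> float:
    """Soft Dice-Sørensen coefficient of channel ``c``.

    ``DSC = (2 * sum(gt_c * pred_c) + eps) / (sum(gt_c) + sum(pred_c) + eps)``
    with the smoothing ``eps`` in both numerator and denominator, so two
    empty channels score a perfect 1.
    """
    gt, pred = _check_pair(gt, pred)
    _check_class(c, gt.shape[2])
    g = gt[..., c]
    p = pred[..., c]
    return float((2.0 * (g * p).sum() + epsilon) /
                 (g.sum() + p.sum() + epsilon))


def dice_loss(gt: np.ndarray, pred: np.ndarray, m: Sequence[float],
              cfg: LossConfig | None = None) -> float:
    """Mask-weighted Dice loss: mean of ``1 - DSC`` over labeled channels.

    Raises if no channel is labeled (the mean would be 0/0).
    """
    cfg = cfg or LossConfig()
    gt, pred = _check_pair(gt, pred)
    m = np.asarray(m, dtype=float)
    if m.shape != (gt.shape[2],):
        raise ValueError(f"mask vector length {m.shape} != C={gt.shape[2]}")
    n_labeled = m.sum()
    if n_labeled < 1:
        raise ValueError("no labeled class: every m_c is 0, the Dice loss "
                         "is undefined for a fully unlabeled sample")
    inter = (gt * pred).sum(axis=(0, 1))
    sums = gt.sum(axis=(0, 1)) + pred.sum(axis=(0, 1))
    dsc = (2.0 * inter + cfg.epsilon) / (sums + cfg.epsilon)
    return float((m * (1.0 - dsc)).sum() / n_labeled)


def _cal_weights(m: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Per-channel weight ``(1 - m_z)`` with the background zeroed out."""
    w = 1.0 - m
    if cfg.background_index is not None:
        w = w.copy()
        w[cfg.background_index] = 0.0
    return w


def cal_class(gt: np.ndarray, pred: np.ndarray, m: Sequence[float], c: int,
              cfg: LossConfig | None = None) -> float:
    """Class-asymmetric penalty for labeled class ``c``.

    Sums, over the pixels where ``gt[..., c] == 1``, the activated predicted
    values of all *unlabeled* channels ``z != c`` (background excluded).
    """
    cfg = cfg or LossConfig()
    gt, pred = _check_pair(gt, pred)
    m = np.asarray(m, dtype=float)
    _check_class(c, gt.shape[2])
    w = _cal_weights(m, cfg)
    w = w.copy()
    w[c] = 0.0  # never compare a channel against itself
    inner = (cfg.f(pred) * w).sum(axis=-1)
    val = float((gt[..., c] * inner).sum())
    if cfg.normalize_cal:
        val /= gt.shape[0] * gt.shape[1]
    return val


def cal_loss(gt: np.ndarray, pred: np.ndarray, m: Sequence[float],
             cfg: LossConfig | None = None) -> float:
    """Total class-asymmetric loss: sum of ``cal_class`` over labeled,
    non-background classes.  Zero for a fully labeled sample."""
    cfg = cfg or LossConfig()
    gt, pred = _check_pair(gt, pred)
    m = np.asarray(m, dtype=float)
    total = 0.0
    for c in range(gt.shape[2]):
        if m[c] < 0.5:
            continue
        if cfg.background_index is not None and c == cfg.background_index:
            continue
        total += cal_class(gt, pred, m, c, cfg)
    return total


def loss_components(gt: np.ndarray, pred: np.ndarray, m: Sequence[float],
                    cfg: LossConfig) -> tuple[float, float, float]:
    """Return ``(L, L_DSC, L_CAL)`` for one sample."""
    l_dsc = dice_loss(gt, pred, m, cfg)
    l_cal = cal_loss(gt, pred, m, cfg)
    return (1.0 - cfg.alpha) * l_dsc + cfg.alpha * l_cal, l_dsc, l_cal


def combined_loss(gt: np.ndarray, pred: np.ndarray, m: Sequence[float],
                  cfg: LossConfig) -> float:
    """Combined objective ``L = (1 - alpha) * L_DSC + alpha * L_CAL``."""
    return loss_components(gt, pred, m, cfg)[0]


def loss_and_grad(gt: np.ndarray, pred: np.ndarray, m: Sequence[float],
                  cfg: LossConfig):
    """Combined loss and its analytic gradient w.r.t. the prediction array.

    Returns ``((L, L_DSC, L_CAL), dL/dpred)``.  The Dice term only touches
    labeled channels; the asymmetric term only unlabeled, non-background
    channels — so with ``alpha = 0`` the gradient on unlabeled channels is
    exactly zero.
    """
    gt, pred = _check_pair(gt, pred)
    m = np.asarray(m, dtype=float)
    n_labeled = m.sum()
    if n_labeled < 1:
        raise ValueError("no labeled class")
    grad = np.zeros_like(pred)

    inter = (gt * pred).sum(axis=(0, 1))
    num = 2.0 * inter + cfg.epsilon
    den = gt.sum(axis=(0, 1)) + pred.sum(axis=(0, 1)) + cfg.epsilon
    dsc = num / den
    l_dsc = float((m * (1.0 - dsc)).sum() / n_labeled)
    # d(1 - DSC_c)/d pred_{uvc} = -(2 gt - DSC) / den
    coef = (1.0 - cfg.alpha) * m / (n_labeled * den)
    grad -= coef * (2.0 * gt - dsc)

    w = _cal_weights(m, cfg)
    labeled = m.copy()
    if cfg.background_index is not None:
        labeled[cfg.background_index] = 0.0
    # pixels carrying any labeled (non-background) ground truth
    gsum = (gt * labeled).sum(axis=-1)
    scale = 1.0 / (gt.shape[0] * gt.shape[1]) if cfg.normalize_cal else 1.0
    l_cal = float((gsum * (cfg.f(pred) * w).sum(axis=-1)).sum()) * scale
    if cfg.alpha > 0.0:
        grad += (cfg.alpha * scale) * gsum[..., None] * w * cfg.f_grad(pred)

    loss = (1.0 - cfg.alpha) * l_dsc + cfg.alpha * l_cal
    return (loss, l_dsc, l_cal), grad


def batch_loss_and_grad(gt: np.ndarray, pred: np.ndarray, m: np.ndarray,
                        cfg: LossConfig):
    """Per-sample combined loss averaged over a batch, with gradient.

    Each sample keeps its own mask vector, so the per-sample normalisation
    by the number of present masks stays correct when ``m`` varies within
    the batch.  Returns ``((L, L_DSC, L_CAL), dL/dpred)`` with the gradient
    already divided by the batch size.
    """
    gt = np.asarray(gt, dtype=np.float32)
    pred = np.asarray(pred, dtype=np.float32)
    m = np.asarray(m, dtype=np.float32)
    if gt.ndim != 4:
        raise ValueError("batch arrays must be (N, h, w, C)")
    n = gt.shape[0]
    n_labeled = m.sum(axis=1)
    if np.any(n_labeled < 1):
        raise ValueError("batch contains a fully unlabeled sample")
    grad = np.empty_like(pred)

    inter = (gt * pred).sum(axis=(1, 2))
    num = 2.0 * inter + cfg.epsilon
    den = gt.sum(axis=(1, 2)) + pred.sum(axis=(1, 2)) + cfg.epsilon
    dsc = num / den
    l_dsc = float(((m * (1.0 - dsc)).sum(axis=1) / n_labeled).mean())
    coef = (1.0 - cfg.alpha) * m / (n_labeled[:, None] * den)
    grad[:] = -coef[:, None, None, :] * (2.0 * gt - dsc[:, None, None, :])

    w = np.float32(1.0) - m
    labeled = m.copy()
    if cfg.background_index is not None:
        w[:, cfg.background_index] = 0.0
        labeled[:, cfg.background_index] = 0.0
    gsum = (gt * labeled[:, None, None, :]).sum(axis=-1)
    scale = 1.0 / (gt.shape[1] * gt.shape[2]) if cfg.normalize_cal else 1.0
    fp = cfg.f(pred)
    l_cal = float((gsum[..., None] * fp * w[:, None, None, :]).sum() / n) * scale
    if cfg.alpha > 0.0:
        grad += (cfg.alpha * scale) * gsum[..., None] * \
            w[:, None, None, :] * cfg.f_grad(pred)

    grad /= n
    loss = (1.0 - cfg.alpha) * l_dsc + cfg.alpha * l_cal
    return (loss, l_dsc, l_cal), grad.astype(np.float32)


def iou_class(gt: np.ndarray, pred_binary: np.ndarray, c: int) -> float:
    """Intersection over union of binary channel ``c``; 1.0 if both empty."""
    gt, pred_binary = _check_pair(gt, pred_binary)
    _check_class(c, gt.shape[2])
    g = gt[..., c] > 0.5
    p = pred_binary[..., c] > 0.5
    union = np.logical_or(g, p).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(g, p).sum() / union)


def pfr(inp: PFRInput | float, total_samples: int | None = None,
        dropped_labels: int = 0) -> float:
    """Performance Frugality Ratio ``PFR(M) = M / n`` with ``n = S - P``.

    Accepts either a :class:`PFRInput` or ``pfr(statistic, S, P)``.
    """
    if isinstance(inp, PFRInput):
        stat, n = inp.statistic, inp.available_labels
    else:
        if total_samples is None:
            raise TypeError("pfr(statistic, total_samples, dropped_labels)")
        stat, n = float(inp), total_samples - dropped_labels
    if n < 1:
        raise ValueError(f"number of available labels must be >= 1, got {n}")
    return stat / n


def evaluate_dataset(samples, foreground_classes: Sequence[int],
                     cfg: LossConfig | None = None,
                     available_labels: int | None = None) -> dict:
    """Per-class and mean DSC/IoU (and mean PFR) over evaluation samples.

    ``samples`` is a sequence of ``(ground_truth, prediction)`` pairs with
    fully labeled ground truths; predictions are binarised by per-pixel
    argmax before scoring.  Means are over ``foreground_classes`` only;
    when ``available_labels`` (the training-set label count ``n = S - P``)
    is given, the report includes ``mpfr_dsc = mdsc / n`` and likewise for
    IoU.
    """
    from .model import hard_masks  # local import to avoid a cycle

    cfg = cfg or LossConfig()
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to evaluate")
    C = np.asarray(samples[0][0]).shape[2]
    dsc_acc = np.zeros(C)
    iou_acc = np.zeros(C)
    for gt, pred in samples:
        gt = np.asarray(gt, dtype=float)
        hard = hard_masks(np.asarray(pred, dtype=float)[None])[0]
        for c in range(C):
            dsc_acc[c] += dsc_class(gt, hard, c, cfg.epsilon)
            iou_acc[c] += iou_class(gt, hard, c)
    dsc_acc /= len(samples)
    iou_acc /= len(samples)
    fg = list(foreground_classes)
    report = {
        "per_class_dsc": {c: float(dsc_acc[c]) for c in range(C)},
        "per_class_iou": {c: float(iou_acc[c]) for c in range(C)},
        "mdsc": float(dsc_acc[fg].mean()),
        "miou": float(iou_acc[fg].mean()),
        "n_samples": len(samples),
    }
    if available_labels is not None:
        report["mpfr_dsc"] = pfr(report["mdsc"], available_labels)
        report["mpfr_iou"] = pfr(report["miou"], available_labels)
    return report
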