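"""Desk-scale experiment harness for training on heterogeneous labels.

Four experiment designs probe how missing labels affect multi-class
segmentation performance, each run on the synthetic shape benchmark
(:mod:`frugalseg.synthetic`) with the tiny network configuration:

* **ablation** — drop labels of *all* foreground classes equally at an
  increasing share rho; the rho = 0 row is the plain supervised baseline.
* **transfer** — one class stays fully labeled while a "new" class loses an
  increasing share of its labels (extending a single-class dataset by a
  second class).
* **merge** — split the dataset into two halves, each labeled with exactly
  one class, and train on their union with oversampling so both sides are
  drawn at equal rates.
* **alpha_sweep** — the transfer setup at a fixed drop share, sweeping the
  weight alpha between the Dice and the class-asymmetric loss terms.

Evaluation always uses the fully labeled test split (heterogenisation never
touches test labels) and reports per-class and mean DSC/IoU plus the mean
Performance Frugality Ratio given the training-set label counts.  Results
come back as a tidy :class:`pandas.DataFrame` with one row per
(configuration, run, class) plus mean/std aggregates over runs.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hetgen import DropSpec, HeterogeneousView, round_half_away
from .model import TrainConfig, UNet, predict, tiny_config, train
from .objective import LossConfig, evaluate_dataset
from .synthetic import SynthConfig, generate_arrays

__all__ = [
    "ExperimentSpec",
    "run_ablation",
    "run_transfer",
    "run_merge",
    "run_alpha_sweep",
    "run_experiment",
    "label_budget",
    "make_equal_sampler",
]

DEFAULT_ALPHA = 0.4  # the empirically best weighting of the two loss terms


@dataclass
class ExperimentSpec:
    """One experiment family plus its sweep values and base configurations."""

    kind: str
    sweep: tuple[float, ...]
    runs: int = 3
    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    new_class: int = 0           # the partially labeled class in transfer
    retained_class: int = 1      # the fully labeled class in transfer
    # CAL divided by w*h so alpha weighs two comparably scaled terms; with
    # the raw pixel-count sum any alpha > ~0.01 acts like alpha ~= 1
    normalize_cal: bool = True
    synth: SynthConfig | None = None
    train_cfg: TrainConfig | None = None

    def __post_init__(self) -> None:
        kinds = ("ablation", "transfer", "merge", "alpha_sweep")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.kind == "alpha_sweep":
            for a in self.sweep:
                if not 0.0 <= a < 1.0:
                    raise ValueError(f"alpha {a} outside [0, 1)")
        elif self.kind == "merge":
            for p in self.sweep:
                if not 0.0 < p < 1.0:
                    raise ValueError(f"split proportion {p} outside (0, 1)")
        else:
            for r in self.sweep:
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"rho {r} outside [0, 1]")
        if self.synth is None:
            fg = 3 if self.kind == "ablation" else 2
            self.synth = SynthConfig(num_foreground_classes=fg)
        if self.train_cfg is None:
            # desk-scale protocol: small budget, early stopping does the rest
            self.train_cfg = TrainConfig(batch_size=8, max_epochs=10,
                                         patience=3)


def label_budget(n_samples: int, n_classes: int,
                 seconds_per_mask: float = 25.0):
    """Annotation cost of a homogeneous labeling: ``(total_masks, hours)``.

    Every sample needs one mask per class, so ``total_masks = n_samples *
    n_classes``; at ``seconds_per_mask`` seconds each the total effort is
    ``total_masks * seconds_per_mask / 3600`` hours.
    """
    if n_samples < 1 or n_classes < 1:
        raise ValueError("n_samples and n_classes must be positive integers")
    if seconds_per_mask <= 0:
        raise ValueError("seconds_per_mask must be positive")
    total_masks = int(n_samples) * int(n_classes)
    return total_masks, total_masks * seconds_per_mask / 3600.0


def make_equal_sampler(side_of: np.ndarray, audit: list | None = None):
    """Sampler drawing equally from two dataset sides via oversampling.

    ``side_of[i]`` is 0 or 1 for training sample ``i``.  Each epoch the
    minority side is resampled with replacement up to the majority size, so
    both sides contribute exactly the same number of draws; the realised
    per-side counts are appended to ``audit`` when given.
    """
    side_of = np.asarray(side_of)

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        idx0 = np.flatnonzero(side_of[:n] == 0)
        idx1 = np.flatnonzero(side_of[:n] == 1)
        if len(idx0) == 0 or len(idx1) == 0:
            raise ValueError("one side of the merge is empty")
        target = max(len(idx0), len(idx1))

        def blow_up(idx):
            if len(idx) == target:
                return idx
            extra = rng.choice(idx, size=target - len(idx), replace=True)
            return np.concatenate([idx, extra])

        order = np.concatenate([blow_up(idx0), blow_up(idx1)])
        rng.shuffle(order)
        if audit is not None:
            audit.append((int((side_of[order] == 0).sum()),
                          int((side_of[order] == 1).sum())))
        return order

    return sampler


def _train_and_eval(train_data, test_data, synth: SynthConfig,
                    train_cfg: TrainConfig, loss_cfg: LossConfig,
                    seed: int, available_labels: int, *, sampler=None):
    net = UNet(tiny_config(synth.image_size, synth.num_classes), seed=seed)
    cfg = replace(train_cfg, seed=seed)
    net, history = train(net, train_data, cfg, loss_cfg, sampler=sampler)
    images = np.stack([s[0] for s in test_data])
    preds = predict(net, images, batch_size=cfg.batch_size)
    report = evaluate_dataset(
        [(gt, p) for (_, gt, _), p in zip(test_data, preds)],
        foreground_classes=range(synth.num_foreground_classes),
        cfg=loss_cfg, available_labels=available_labels)
    report["epochs_trained"] = len(history)
    return report


def _rows_from_report(report, config_label, config_value, run, seed,
                      class_names):
    rows = []
    for c, name in enumerate(class_names):
        rows.append({
            "config": config_label, "value": config_value, "run": run,
            "seed": seed, "class": name,
            "dsc": report["per_class_dsc"][c],
            "iou": report["per_class_iou"][c],
        })
    rows.append({
        "config": config_label, "value": config_value, "run": run,
        "seed": seed, "class": "mean",
        "dsc": report["mdsc"], "iou": report["miou"],
        "mpfr_dsc": report.get("mpfr_dsc"),
        "mpfr_iou": report.get("mpfr_iou"),
    })
    return rows


def _aggregate(df: pd.DataFrame) -> pd.DataFrame:
    stats = (df.groupby(["config", "value", "class"], sort=False)
             .agg(dsc_mean=("dsc", "mean"), dsc_std=("dsc", "std"),
                  iou_mean=("iou", "mean"), iou_std=("iou", "std"),
                  mpfr_dsc=("mpfr_dsc", "mean"), mpfr_iou=("mpfr_iou", "mean"),
                  runs=("run", "count"))
             .reset_index())
    return stats


def _heterogenize(train_full, drop_classes, rho, seed, num_classes,
                  background_index):
    """Fixed heterogeneous copy of an in-memory training set."""
    ids = list(range(len(train_full)))
    spec = DropSpec(drop_classes=tuple(drop_classes), rho=rho, seed=seed,
                    persistence="whole_training")
    view = HeterogeneousView(ids, num_classes, spec,
                             background_index=background_index)
    out = []
    for i, (img, gt, _) in enumerate(train_full):
        gt2, m = view.apply(i, gt)
        out.append((img, gt2, m))
    return out, view


def _fg_class_names(synth: SynthConfig):
    base = ["atrium", "ventricle", "bulbus", "class3", "class4"]
    return base[:synth.num_foreground_classes] + ["background"]


def run_ablation(spec: ExperimentSpec) -> pd.DataFrame:
    """Drop labels of all foreground classes equally across a rho sweep."""
    if 0.0 not in spec.sweep:
        raise ValueError("the ablation sweep must include rho = 0 (baseline)")
    synth = spec.synth
    loss_cfg = LossConfig(alpha=spec.alpha,
                          background_index=synth.background_index,
                          normalize_cal=spec.normalize_cal)
    names = _fg_class_names(synth)
    fg = list(range(synth.num_foreground_classes))
    rows = []
    for run in range(spec.runs):
        seed = spec.seed + run
        train_full, test = generate_arrays(replace(synth, seed=seed))
        S = len(train_full)
        for rho in spec.sweep:
            het, _ = _heterogenize(train_full, fg, rho, seed,
                                   synth.num_classes, synth.background_index)
            P = round_half_away(rho * S)
            n_avail = (S - P) * len(fg)
            report = _train_and_eval(het, test, synth, spec.train_cfg,
                                     loss_cfg, seed, n_avail)
            rows += _rows_from_report(report, "rho", rho, run, seed, names)
    df = pd.DataFrame(rows)
    return _aggregate(df), df


def run_transfer(spec: ExperimentSpec) -> pd.DataFrame:
    """Keep one class fully labeled, drop a share of the new class's labels."""
    synth = spec.synth
    if spec.new_class == spec.retained_class:
        raise ValueError("new_class and retained_class must differ")
    loss_cfg = LossConfig(alpha=spec.alpha,
                          background_index=synth.background_index,
                          normalize_cal=spec.normalize_cal)
    names = _fg_class_names(synth)
    fg = list(range(synth.num_foreground_classes))
    rows = []
    for run in range(spec.runs):
        seed = spec.seed + run
        train_full, test = generate_arrays(replace(synth, seed=seed))
        S = len(train_full)
        for rho in spec.sweep:
            het, _ = _heterogenize(train_full, [spec.new_class], rho, seed,
                                   synth.num_classes, synth.background_index)
            P = round_half_away(rho * S)
            n_avail = S * (len(fg) - 1) + (S - P)
            report = _train_and_eval(het, test, synth, spec.train_cfg,
                                     loss_cfg, seed, n_avail)
            rows += _rows_from_report(report, "rho", rho, run, seed, names)
    df = pd.DataFrame(rows)
    return _aggregate(df), df


def run_merge(spec: ExperimentSpec, audit: list | None = None) -> pd.DataFrame:
    """Merge two single-class-labeled dataset halves with oversampling.

    At proportion p, the first ``round(p * S)`` training samples keep only
    the ``new_class`` label and the rest only the ``retained_class`` label;
    an equal-rate sampler oversamples the minority side each epoch.
    """
    synth = spec.synth
    loss_cfg = LossConfig(alpha=spec.alpha,
                          background_index=synth.background_index,
                          normalize_cal=spec.normalize_cal)
    names = _fg_class_names(synth)
    bg = synth.background_index
    rows = []
    for run in range(spec.runs):
        seed = spec.seed + run
        train_full, test = generate_arrays(replace(synth, seed=seed))
        S = len(train_full)
        for prop in spec.sweep:
            n_a = round_half_away(prop * S)
            if n_a == 0 or n_a == S:
                raise ValueError(f"proportion {prop} leaves one side empty")
            rng = np.random.default_rng([spec.seed, run])
            perm = rng.permutation(S)
            side_of = np.zeros(S, dtype=int)
            side_of[perm[n_a:]] = 1
            het = []
            for i, (img, gt, _) in enumerate(train_full):
                keep = spec.new_class if side_of[i] == 0 else spec.retained_class
                gt2 = gt.copy()
                m = np.zeros(synth.num_classes, dtype=np.uint8)
                m[keep] = 1
                m[bg] = 1
                for c in range(synth.num_foreground_classes):
                    if c != keep:
                        gt2[..., c] = 0
                gt2[..., bg] = 1 - gt2[..., keep]
                het.append((img, gt2, m))
            sampler = make_equal_sampler(side_of, audit)
            # each side contributes S - n_side labels; one label per sample
            n_avail = S
            report = _train_and_eval(het, test, synth, spec.train_cfg,
                                     loss_cfg, seed, n_avail, sampler=sampler)
            rows += _rows_from_report(report, "proportion", prop, run, seed,
                                      names)
    df = pd.DataFrame(rows)
    return _aggregate(df), df


def run_alpha_sweep(spec: ExperimentSpec, rho: float = 0.5) -> pd.DataFrame:
    """Transfer setup at a fixed drop share, sweeping the loss weight."""
    synth = spec.synth
    names = _fg_class_names(synth)
    fg = list(range(synth.num_foreground_classes))
    rows = []
    for run in range(spec.runs):
        seed = spec.seed + run
        train_full, test = generate_arrays(replace(synth, seed=seed))
        S = len(train_full)
        het, _ = _heterogenize(train_full, [spec.new_class], rho, seed,
                               synth.num_classes, synth.background_index)
        P = round_half_away(rho * S)
        n_avail = S * (len(fg) - 1) + (S - P)
        for alpha in spec.sweep:
            loss_cfg = LossConfig(alpha=alpha,
                                  background_index=synth.background_index,
                                  normalize_cal=spec.normalize_cal)
            report = _train_and_eval(het, test, synth, spec.train_cfg,
                                     loss_cfg, seed, n_avail)
            rows += _rows_from_report(report, "alpha", alpha, run, seed, names)
    df = pd.DataFrame(rows)
    return _aggregate(df), df


_RUNNERS = {
    "ablation": run_ablation,
    "transfer": run_transfer,
    "merge": run_merge,
    "alpha_sweep": run_alpha_sweep,
}


def run_experiment(spec: ExperimentSpec, **kwargs):
    """Dispatch on ``spec.kind``; returns ``(aggregate, per_run)`` tables."""
    return _RUNNERS[spec.kind](spec, **kwargs)
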