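"""Synthetic shape-image benchmark for segmentation with missing labels.

Generates desk-scale RGB images containing one filled ellipse per
foreground class on a dark background — a cartoon of a three-chambered
heart seen in a fixed view: three adjacent, mutually exclusive regions of
distinct colour, one of them (the "hardest class") deliberately smaller and
thinner.  Adjacency matters: the class-asymmetric loss only fires where an
unlabeled channel's prediction can overlap a labeled class's ground truth,
which requires the regions to sit next to each other, as they do in the
anatomy this emulates.

Every sample is fully (homogeneously) labeled; making labels heterogeneous
is :mod:`frugalseg.hetgen`'s job.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import ellipse

__all__ = ["SynthConfig", "generate_sample", "generate_arrays",
           "generate_dataset"]

_DEFAULT_COLORS = (
    (0.85, 0.25, 0.25),   # class 0 — "atrium"-like, reddish
    (0.25, 0.70, 0.30),   # class 1 — "ventricle"-like, greenish
    (0.30, 0.40, 0.85),   # class 2 — "bulbus"-like, bluish
    (0.80, 0.75, 0.25),
    (0.70, 0.30, 0.75),
)
_BACKGROUND_COLOR = (0.08, 0.08, 0.10)


@dataclass
class SynthConfig:
    """Generator settings; the defaults define the desk-scale benchmark.

    ``area_scales`` shrinks individual classes; the last foreground class
    defaults to a smaller, thinner ellipse so one class is measurably
    harder to segment than the others.
    """

    n_samples: int = 200
    image_size: int = 64
    num_foreground_classes: int = 3
    noise_sigma: float = 0.05
    split_fraction: float = 0.2     # share of samples tagged as test
    area_scales: tuple[float, ...] | None = None
    colors: tuple = _DEFAULT_COLORS
    background_color: tuple = _BACKGROUND_COLOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_foreground_classes < 1:
            raise ValueError("need at least one foreground class")
        if self.num_foreground_classes > len(self.colors):
            raise ValueError("not enough distinct colors configured")
        if not 0.0 <= self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in [0, 1)")
        if self.area_scales is None:
            scales = [1.0] * self.num_foreground_classes
            if self.num_foreground_classes >= 3:
                scales[-1] = 0.45   # the hard, thin class
            self.area_scales = tuple(scales)

    @property
    def num_classes(self) -> int:
        """Total channels including the background (last index)."""
        return self.num_foreground_classes + 1

    @property
    def background_index(self) -> int:
        return self.num_foreground_classes


def _place_ellipses(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Rasterise adjacent, pairwise-disjoint ellipses; (h, w, F) uint8.

    The ellipse centres sit on a jittered chain through the image centre so
    consecutive regions are near one another without overlapping; raises
    after 100 failed placement attempts.
    """
    n = cfg.image_size
    F = cfg.num_foreground_classes
    base_r = n / (2.8 * max(F, 2))
    for _ in range(100):
        masks = np.zeros((n, n, F), dtype=np.uint8)
        angle = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.sin(angle), np.cos(angle)])
        center = np.array([n / 2, n / 2]) + rng.uniform(-n / 10, n / 10, 2)
        step = 2.45 * base_r
        offsets = (np.arange(F) - (F - 1) / 2)[:, None] * step * direction
        ok = True
        for c in range(F):
            scale = np.sqrt(cfg.area_scales[c])
            ry = base_r * scale * rng.uniform(0.85, 1.15)
            rx = base_r * scale * rng.uniform(0.85, 1.15)
            if cfg.area_scales[c] < 0.7:
                rx *= 0.6   # thin ellipse for the hard class
            cy, cx = center + offsets[c] + rng.uniform(-1.5, 1.5, 2)
            rr, cc = ellipse(cy, cx, max(ry, 1.5), max(rx, 1.5), shape=(n, n))
            if rr.size == 0:
                ok = False
                break
            masks[rr, cc, c] = 1
        if not ok:
            continue
        if masks.sum(axis=-1).max() <= 1:       # pairwise disjoint
            if all(masks[..., c].any() for c in range(F)):
                return masks
    raise RuntimeError("could not place non-overlapping shapes in 100 tries")


def generate_sample(cfg: SynthConfig, rng: np.random.Generator):
    """One fully labeled sample: ``(image, ground_truth, mask_vector)``.

    The image is float in [0, 1]; the ground truth has one channel per
    foreground class plus a final background channel (the complement), and
    the mask vector is all ones.
    """
    fg = _place_ellipses(cfg, rng)
    n = cfg.image_size
    gt = np.concatenate(
        [fg, (1 - fg.max(axis=-1, keepdims=True)).astype(np.uint8)], axis=-1)
    image = np.empty((n, n, 3), dtype=np.float64)
    image[:] = cfg.background_color
    for c in range(cfg.num_foreground_classes):
        image[fg[..., c] == 1] = cfg.colors[c]
    if cfg.noise_sigma > 0:
        image += rng.normal(0.0, cfg.noise_sigma, image.shape)
        image = np.clip(image, 0.0, 1.0)
    m = np.ones(cfg.num_classes, dtype=np.uint8)
    return image.astype(np.float32), gt, m


def generate_arrays(cfg: SynthConfig):
    """In-memory dataset: ``(train, test)`` lists of (image, gt, m) triples.

    Deterministic in ``cfg.seed``; the test split is a random
    ``split_fraction`` share of the samples.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [generate_sample(cfg, rng) for _ in range(cfg.n_samples)]
    n_test = int(round(cfg.split_fraction * cfg.n_samples))
    test_idx = set(rng.choice(cfg.n_samples, size=n_test,
                              replace=False).tolist())
    train = [s for i, s in enumerate(samples) if i not in test_idx]
    test = [s for i, s in enumerate(samples) if i in test_idx]
    return train, test


def generate_dataset(cfg: SynthConfig, out_dir, *, force: bool = False,
                     class_names=None):
    """Write the dataset to disk as PNGs plus a CSV manifest.

    Layout: ``images/<id>.png`` and ``masks/<id>_<class>.png`` (8-bit,
    values {0, 255}); the manifest binds them with a train/test split.
    Returns the loaded :class:`~frugalseg.data_io.Manifest`.
    """
    from PIL import Image

    from .data_io import Manifest, write_manifest, load_manifest

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} exists and is not empty (pass force=True)")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    if class_names is None:
        defaults = ["atrium", "ventricle", "bulbus", "class3", "class4"]
        class_names = defaults[:cfg.num_foreground_classes]

    rng = np.random.default_rng(cfg.seed)
    rows = []
    samples = [generate_sample(cfg, rng) for _ in range(cfg.n_samples)]
    n_test = int(round(cfg.split_fraction * cfg.n_samples))
    test_idx = set(rng.choice(cfg.n_samples, size=n_test,
                              replace=False).tolist())
    for i, (image, gt, _) in enumerate(samples):
        sid = f"s{i:04d}"
        img_rel = f"images/{sid}.png"
        Image.fromarray(
            np.round(image * 255).astype(np.uint8)).save(out_dir / img_rel)
        row = {"sample_id": sid, "image": img_rel,
               "split": "test" if i in test_idx else "train"}
        for c, name in enumerate(class_names):
            mask_rel = f"masks/{sid}_{name}.png"
            Image.fromarray(
                (gt[..., c] * 255).astype(np.uint8)).save(out_dir / mask_rel)
            row[f"mask_{name}"] = mask_rel
        rows.append(row)

    import pandas as pd
    df = pd.DataFrame(rows)
    manifest = Manifest(df, class_names=list(class_names), root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    return load_manifest(out_dir / "manifest.csv", root=out_dir)
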