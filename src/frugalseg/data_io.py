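"""Dataset I/O: CSV manifests, PNG images/masks, preprocessing, augmentation.

A dataset is a directory of PNG files indexed by a manifest table with the
columns ``sample_id, image, mask_<class1>, ..., mask_<classC>, split``.
Each ``mask_*`` cell holds the path of an 8-bit single-channel PNG (values
{0, 255}) or is blank — a blank cell means the class is unlabeled for that
sample (its mask-vector entry is 0).  Arrays are row-major ``(h, w, ...)``;
the background channel is appended last as the complement of the union of
the *present* foreground masks.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "Manifest",
    "AugmentConfig",
    "load_manifest",
    "write_manifest",
    "read_sample",
    "load_split",
    "augment",
]

_FIXED_COLUMNS = ("sample_id", "image", "split")
_SPLITS = ("train", "test")


@dataclass
class Manifest:
    """A validated manifest table plus the class names it defines."""

    df: pd.DataFrame
    class_names: list[str]
    root: Path | None = None

    def __len__(self) -> int:
        return len(self.df)

    def rows(self, split: str | None = None):
        df = self.df if split is None else self.df[self.df["split"] == split]
        return df.itertuples(index=False)

    def mask_vector(self, row) -> np.ndarray:
        """Foreground availability flags (background channel not included)."""
        return np.array(
            [1 if getattr(row, f"mask_{n}") else 0 for n in self.class_names],
            dtype=np.uint8)

    def availability_counts(self, split: str | None = None) -> dict:
        """Per-class count of labeled samples (and the total row count)."""
        df = self.df if split is None else self.df[self.df["split"] == split]
        counts = {n: int((df[f"mask_{n}"] != "").sum())
                  for n in self.class_names}
        counts["_rows"] = len(df)
        return counts


def load_manifest(path, root=None, *, check_files: bool = True) -> Manifest:
    """Load and validate a CSV manifest.

    Blank cells are kept as empty strings (missing labels).  Validation
    covers required/unknown columns, duplicate sample ids, split tags and
    — unless ``check_files=False`` — existence of every referenced file.
    """
    path = Path(path)
    root = Path(root) if root is not None else path.parent
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns {missing}")
    mask_cols = [c for c in df.columns if c.startswith("mask_")]
    unknown = [c for c in df.columns
               if c not in _FIXED_COLUMNS and c not in mask_cols]
    if unknown:
        raise ValueError(f"manifest {path} has unknown columns {unknown}; "
                         f"expected {_FIXED_COLUMNS} plus mask_<class> columns")
    if not mask_cols:
        raise ValueError(f"manifest {path} defines no mask_<class> columns")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
    bad_split = sorted(set(df["split"]) - set(_SPLITS))
    if bad_split:
        raise ValueError(f"unknown split tags {bad_split}; expected {_SPLITS}")
    if check_files:
        for col in ("image", *mask_cols):
            for p in df[col]:
                if p and not (root / p).exists():
                    raise FileNotFoundError(
                        f"manifest references missing file {root / p}")
    class_names = [c[len("mask_"):] for c in mask_cols]
    manifest = Manifest(df, class_names=class_names, root=root)
    counts = manifest.availability_counts()
    per_class = ", ".join(f"{n}={counts[n]}" for n in class_names)
    logging.getLogger(__name__).info(
        "loaded manifest %s: %d rows, labels per class: %s",
        path, len(df), per_class)
    return manifest


def write_manifest(manifest: Manifest, path) -> None:
    """Write the manifest back to CSV; blank cells stay blank."""
    manifest.df.to_csv(path, index=False)


def _load_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im)


def read_sample(row, manifest: Manifest):
    """Load one manifest row into ``(image, ground_truth, mask_vector)``.

    The image comes back float in [0, 1] with shape ``(h, w, 3)``; the
    ground truth as ``(h, w, C+1)`` uint8 with masks binarised at 128 and
    the background appended as complement of the union of present masks;
    the mask vector has length C+1 with the background flag always 1.
    Absent masks give all-zero channels with a 0 flag.  Overlapping
    foreground masks trigger a mutual-exclusivity warning.
    """
    root = manifest.root or Path(".")
    img = _load_png(root / row.image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"{row.image}: expected an RGB image")
    image = img[..., :3].astype(np.float32) / 255.0
    h, w = image.shape[:2]

    F = len(manifest.class_names)
    gt = np.zeros((h, w, F + 1), dtype=np.uint8)
    m = np.ones(F + 1, dtype=np.uint8)
    for c, name in enumerate(manifest.class_names):
        rel = getattr(row, f"mask_{name}")
        if not rel:
            m[c] = 0
            continue
        mask = _load_png(root / rel)
        if mask.ndim != 2:
            raise ValueError(f"{rel}: mask must be single-channel")
        if mask.shape != (h, w):
            raise ValueError(f"{rel}: mask size {mask.shape} does not match "
                             f"image size {(h, w)}")
        gt[..., c] = (mask >= 128).astype(np.uint8)
    fg_present = [c for c in range(F) if m[c]]
    if fg_present and gt[..., fg_present].sum(axis=-1).max() > 1:
        warnings.warn(f"sample {row.sample_id}: overlapping foreground masks "
                      "violate mutual exclusivity", stacklevel=2)
    if fg_present:
        gt[..., F] = 1 - gt[..., fg_present].max(axis=-1)
    else:
        gt[..., F] = 1
    return image, gt, m


def load_split(manifest: Manifest, split: str):
    """All samples of one split as a list of (image, gt, m) triples."""
    return [read_sample(row, manifest) for row in manifest.rows(split)]


@dataclass
class AugmentConfig:
    """Geometric augmentation recipe applied identically to an image and
    all of its mask channels.

    The rotation and shear ranges are deliberately tiny (fractions of a
    degree) — the imaging view this models is mechanically fixed, so only
    minimal geometric variation is plausible.  ``zoom_range`` z draws a
    scale factor uniformly from [1 - z, 1 + z].
    """

    rotation_range: float = 0.3        # degrees, drawn from [0, range]
    width_shift: float = 0.05          # fraction of width, [-s, s]
    height_shift: float = 0.05
    shear_range: float = 0.05          # degrees counter-clockwise, [0, range]
    zoom_range: float = 0.5
    horizontal_flip_prob: float = 0.5
    fill_mode: str = "nearest"
    target_size: tuple[int, int] = (256, 256)


def augment(image: np.ndarray, gt: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator):
    """One random augmentation draw; returns ``(image, ground_truth)``.

    Image and every mask channel receive the same affine transform; masks
    are warped with nearest-neighbour interpolation and re-binarised so
    binarity and the foreground/background partition survive.  Finally
    both are resized to ``cfg.target_size`` with intensities in [0, 1].
    """
    h, w = image.shape[:2]
    rot = np.deg2rad(rng.uniform(0.0, cfg.rotation_range))
    shear = -np.deg2rad(rng.uniform(0.0, cfg.shear_range))  # ccw positive
    zoom = rng.uniform(1.0 - cfg.zoom_range, 1.0 + cfg.zoom_range)
    tx = rng.uniform(-cfg.width_shift, cfg.width_shift) * w
    ty = rng.uniform(-cfg.height_shift, cfg.height_shift) * h
    flip = rng.random() < cfg.horizontal_flip_prob

    center = np.array([w / 2, h / 2])
    tform = (AffineTransform(translation=-center)
             + AffineTransform(rotation=rot, shear=shear,
                               scale=(zoom, zoom))
             + AffineTransform(translation=center + (tx, ty)))
    mode = "edge" if cfg.fill_mode == "nearest" else cfg.fill_mode

    out_img = warp(image, tform.inverse, order=1, mode=mode,
                   preserve_range=True)
    out_gt = warp(gt.astype(np.float32), tform.inverse, order=0, mode=mode,
                  preserve_range=True)
    if flip:
        out_img = out_img[:, ::-1]
        out_gt = out_gt[:, ::-1]

    th, tw = cfg.target_size
    if (h, w) != (th, tw):
        out_img = resize(out_img, (th, tw), order=1, mode="edge",
                         anti_aliasing=True, preserve_range=True)
        out_gt = resize(out_gt, (th, tw), order=0, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    out_gt = (out_gt >= 0.5).astype(np.uint8)
    return np.clip(out_img, 0.0, 1.0).astype(np.float32), out_gt
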