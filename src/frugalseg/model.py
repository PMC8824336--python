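"""U-Net-style encoder-decoder segmentation network and training loop.

The network is a symmetric fully convolutional encoder-decoder with skip
connections: each encoder stage applies two 3x3 convolutions (ReLU) and a
2x2 max pool; the decoder mirrors it with nearest-neighbour upsampling and
channel concatenation of the encoder feature map at the same resolution; a
1x1 convolution followed by a per-pixel softmax produces a probability
simplex over the classes at every pixel.  Implemented directly on NumPy
(see :mod:`frugalseg.nn`), which keeps the whole pipeline dependency-light
and CPU-friendly at desk scale.

Training minimises the combined objective for heterogeneous labels
(:func:`frugalseg.objective.combined_loss`) with Adam, early-stopping on the
masked Dice loss measured on a held-out validation split, as is standard for
this family of models.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .objective import LossConfig, batch_loss_and_grad, dice_loss

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "UNet",
    "build_network",
    "parameter_count",
    "train",
    "predict",
    "hard_masks",
]


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``depth`` encoder stages halve the resolution each, so both input
    dimensions must be divisible by ``2**depth``.  The full-scale default
    (depth 4, 64 base filters) has on the order of 3e7 parameters; the tiny
    configuration used throughout the tests is ``depth=2, base_filters=8``.
    """

    input_size: tuple[int, int] = (256, 256)
    num_classes: int = 4  # including background
    depth: int = 4
    base_filters: int = 64

    def __post_init__(self) -> None:
        h, w = self.input_size
        f = 2 ** self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2**depth={f}")
        if self.num_classes < 2:
            raise ValueError("need at least two classes (incl. background)")


def tiny_config(image_size: int = 64, num_classes: int = 4) -> NetworkConfig:
    """Desk-scale network configuration for tests and synthetic experiments."""
    return NetworkConfig(input_size=(image_size, image_size),
                         num_classes=num_classes, depth=2, base_filters=8)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 11
    max_epochs: int = 50
    patience: int = 5          # early stopping on validation Dice loss
    validation_fraction: float = 0.1
    runs: int = 1
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


class UNet:
    """Encoder-decoder network mapping (N, h, w, 3) -> (N, h, w, C) simplex."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        C = cfg.num_classes
        f = cfg.base_filters

        def block(c_in, c_out):
            return [nn.Conv2D(c_in, c_out, rng=rng), nn.InstanceNorm(c_out),
                    nn.ReLU(),
                    nn.Conv2D(c_out, c_out, rng=rng), nn.InstanceNorm(c_out),
                    nn.ReLU()]

        self.enc = []
        c_in = 3
        for d in range(cfg.depth):
            self.enc.append(block(c_in, f * 2 ** d))
            c_in = f * 2 ** d
        self.pools = [nn.MaxPool2() for _ in range(cfg.depth)]
        self.bottleneck = block(c_in, f * 2 ** cfg.depth)
        c_in = f * 2 ** cfg.depth
        self.ups = [nn.Upsample2() for _ in range(cfg.depth)]
        self.cats = [nn.Concat() for _ in range(cfg.depth)]
        self.dec = []
        for d in reversed(range(cfg.depth)):
            skip_c = f * 2 ** d
            self.dec.append(block(c_in + skip_c, skip_c))
            c_in = skip_c
        self.head = nn.Conv2D(c_in, C, kernel_size=1, rng=rng)

    # -- parameter plumbing ------------------------------------------------
    def _convs(self):
        for blk in self.enc + [self.bottleneck] + self.dec:
            for layer in blk:
                if isinstance(layer, (nn.Conv2D, nn.InstanceNorm)):
                    yield layer
        yield self.head

    @property
    def params(self):
        out = []
        for conv in self._convs():
            out.extend(conv.params)
        return out

    @property
    def grads(self):
        out = []
        for conv in self._convs():
            out.extend(conv.grads)
        return out

    @property
    def num_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:3] != self.cfg.input_size or x.shape[3] != 3:
            raise ValueError(
                f"expected input (N, {self.cfg.input_size[0]}, "
                f"{self.cfg.input_size[1]}, 3), got {x.shape}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            for layer in blk:
                x = layer.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for layer in self.bottleneck:
            x = layer.forward(x)
        for blk, up, cat, skip in zip(self.dec, self.ups, self.cats,
                                      reversed(skips)):
            x = cat.forward(skip, up.forward(x))
            for layer in blk:
                x = layer.forward(x)
        logits = self.head.forward(x)
        self._probs = nn.softmax(logits)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        d = self.head.backward(nn.softmax_backward(self._probs, dprobs))
        for blk, up, cat in zip(reversed(self.dec), reversed(self.ups),
                                reversed(self.cats)):
            for layer in reversed(blk):
                d = layer.backward(d)
            dskip, dup = cat.backward(d)
            d = up.backward(dup)
            # gradient into the matching encoder stage via the skip path
            # is merged below when the encoder backward pass reaches it
            cat._dskip = dskip
        for layer in reversed(self.bottleneck):
            d = layer.backward(d)
        # cats are decoder-ordered (deepest first), so the deepest encoder
        # stage pairs with cats[0]
        for blk, pool, cat in zip(reversed(self.enc), reversed(self.pools),
                                  self.cats):
            d = pool.backward(d)
            d = d + cat._dskip
            for layer in reversed(blk):
                d = layer.backward(d)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def build_network(cfg: NetworkConfig, seed: int = 0) -> UNet:
    """Construct a randomly initialised network for the given configuration."""
    return UNet(cfg, seed=seed)


def parameter_count(cfg: NetworkConfig) -> int:
    """Parameter count of :func:`build_network` without allocating weights."""
    total = 0
    f = cfg.base_filters

    def conv(ci, co, k=3):
        return k * k * ci * co + co

    norm = lambda co: 4 * co  # two InstanceNorms (gain + bias) per block
    c_in = 3
    for d in range(cfg.depth):
        co = f * 2 ** d
        total += conv(c_in, co) + conv(co, co) + norm(co)
        c_in = co
    co = f * 2 ** cfg.depth
    total += conv(c_in, co) + conv(co, co) + norm(co)
    c_in = co
    for d in reversed(range(cfg.depth)):
        skip = f * 2 ** d
        total += conv(c_in + skip, skip) + conv(skip, skip) + norm(skip)
        c_in = skip
    total += conv(c_in, cfg.num_classes, k=1)
    return total


def _as_batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _stack(data, idx):
    x = np.stack([data[i][0] for i in idx]).astype(np.float32)
    y = np.stack([data[i][1] for i in idx]).astype(np.float32)
    m = np.stack([data[i][2] for i in idx]).astype(np.float32)
    return x, y, m


def train(model: UNet, train_data, cfg: TrainConfig, loss_cfg: LossConfig,
          *, val_data=None, epoch_callback=None, sampler=None):
    """Train ``model`` on ``(image, ground_truth, mask_vector)`` triples.

    ``train_data`` is either a sequence of triples or a callable
    ``epoch -> sequence`` (for online label dropping or augmentation, where
    the realised training set may change between epochs).  When ``val_data``
    is None a ``validation_fraction`` split of epoch-0 data is held out.
    ``sampler(rng, n) -> index array`` overrides the default shuffled
    one-pass-per-epoch order (used for oversampling when merging datasets).

    Returns ``(model, history)`` where history is a list of per-epoch dicts
    with train ``loss``/``dice_loss``/``cal_loss`` and ``val_dice_loss``.
    Early stopping monitors the validation Dice loss and restores the best
    weights.
    """
    rng = np.random.default_rng(cfg.seed)
    get_epoch = train_data if callable(train_data) else (lambda e: train_data)

    data0 = list(get_epoch(0))
    if not data0:
        raise ValueError("empty training stream")
    if val_data is None:
        n_val = max(1, int(round(cfg.validation_fraction * len(data0)))) \
            if len(data0) > 1 else 0
        perm = rng.permutation(len(data0))
        val_idx = set(perm[:n_val].tolist())
        val_data = [data0[i] for i in sorted(val_idx)]
        train_idx = [i for i in range(len(data0)) if i not in val_idx]
    else:
        val_data = list(val_data)
        train_idx = list(range(len(data0)))

    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0

    for epoch in range(cfg.max_epochs):
        epoch_data = list(get_epoch(epoch)) if epoch else data0
        data = [epoch_data[i] for i in train_idx]
        if not data:
            raise ValueError("training stream exhausted before one batch")
        if sampler is not None:
            order = np.asarray(sampler(rng, len(data)))
        else:
            order = rng.permutation(len(data))
        tot = np.zeros(3)
        n_batches = 0
        for idx in _as_batches(len(order), cfg.batch_size, order):
            x, y, m = _stack(data, idx)
            probs = model.forward(x)
            (loss, l_dsc, l_cal), dprobs = batch_loss_and_grad(
                y, probs, m, loss_cfg)
            model.backward(dprobs)
            opt.step(model.grads)
            tot += (loss, l_dsc, l_cal)
            n_batches += 1
        rec = {"epoch": epoch,
               "loss": tot[0] / n_batches,
               "dice_loss": tot[1] / n_batches,
               "cal_loss": tot[2] / n_batches}

        if val_data:
            vl = 0.0
            for i in range(0, len(val_data), cfg.batch_size):
                x, y, m = _stack(val_data, range(i, min(i + cfg.batch_size,
                                                        len(val_data))))
                probs = model.forward(x)
                vl += sum(dice_loss(y[j], probs[j], m[j], loss_cfg)
                          for j in range(len(x)))
            rec["val_dice_loss"] = vl / len(val_data)
        else:
            rec["val_dice_loss"] = rec["dice_loss"]
        history.append(rec)
        if cfg.verbose:
            print(f"epoch {epoch:3d}  L={rec['loss']:.4f}  "
                  f"L_DSC={rec['dice_loss']:.4f}  "
                  f"val L_DSC={rec['val_dice_loss']:.4f}")
        if epoch_callback is not None:
            epoch_callback(epoch, rec)

        if rec["val_dice_loss"] < best_val - 1e-5:
            best_val = rec["val_dice_loss"]
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    model.set_weights(best_weights)
    return model, history


def predict(model: UNet, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Soft predictions (per-pixel class simplex) for a batch of images."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    out = []
    for i in range(0, len(images), batch_size):
        out.append(model.forward(images[i:i + batch_size]).copy())
    return np.concatenate(out, axis=0)


def hard_masks(probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax one-hot labelling; ties break to the lowest index."""
    lab = np.argmax(probs, axis=-1)
    return np.eye(probs.shape[-1], dtype=np.uint8)[lab]
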