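"""Vertebra segmentation: encoder-decoder networks and a classical fallback.

Three network variants share one encoder-decoder topology with
concatenation skip connections (no crop-and-copy):

* ``unet``     — two conv units (3x3 conv -> ReLU -> batch norm) per level;
* ``residual`` — a pre-activation residual block per level,
                 x_{l+1} = x_l + F(x_l) with F two BN -> ReLU -> conv units
                 (1x1 projection on the skip when channel counts differ);
* ``dense``    — an l-layer dense block of growth rate k per level, each
                 layer consuming the concatenation of all previous
                 outputs and the block emitting l*k channels, followed by
                 a 1x1 transition back to the level's nominal width.

The decoder upsamples by 2x2 stride-2 transposed convolution, halves the
channels with a 3x3 convolution, concatenates the matching encoder map,
and applies the variant's block.  A 1x1 convolution plus logistic
squashing produces the probability map; masks come from thresholding at
0.5 (configurable).  Training minimises the mean squared error between
the probability map and the binary mask with Adam (batch 10, learning
rate 0.01 by default).

``classical_segment`` is a training-free alternative (Otsu threshold,
central-component selection, hole filling) so the full measurement
pipeline runs without any fitted weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from . import nn
from .metrics import evaluate

__all__ = [
    "NetworkSpec", "TrainingConfig", "build_network", "conv_unit",
    "ResidualBlock", "DenseBlock", "l2_loss", "train", "predict_mask",
    "predict_proba", "crossvalidate", "classical_segment", "augment",
]


@dataclass
class NetworkSpec:
    """Architecture hyper-parameters shared by the three variants."""

    variant: str = "unet"  # unet | residual | dense
    input_shape: tuple[int, int] = (256, 128)
    depth: int = 4  # encoder levels (pooling steps)
    base_channels: int = 8  # channels at the top level; doubles per level
    growth_rate: int = 4  # dense variant: channels added per dense layer
    dense_layers_per_block: int = 4

    def __post_init__(self) -> None:
        if self.variant not in ("unet", "residual", "dense"):
            raise ValueError(f"unknown variant {self.variant!r}")
        h, w = self.input_shape
        if h % (2**self.depth) or w % (2**self.depth):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {2**self.depth}"
            )


@dataclass
class TrainingConfig:
    """Optimisation recipe; defaults follow the reference protocol."""

    batch_size: int = 10
    learning_rate: float = 0.01
    epochs: int = 100
    augmentation_target: int = 1000  # training images per fold after augmentation
    validation_fraction: float = 0.10
    folds: int = 5
    seed: int = 0
    rotation_deg: float = 5.0
    translation_px: float = 5.0
    intensity_scale: tuple[float, float] = (0.9, 1.1)


def conv_unit(in_ch: int, out_ch: int, rng) -> nn.Sequential:
    """3x3 convolution -> ReLU -> batch normalisation."""
    return nn.Sequential(nn.Conv2D(in_ch, out_ch, 3, rng), nn.ReLU(), nn.BatchNorm2D(out_ch))


class ResidualBlock(nn.Layer):
    """Pre-activation residual block: x + F(x), F = (BN -> ReLU -> conv) x2."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        self.branch = nn.Sequential(
            nn.BatchNorm2D(in_ch), nn.ReLU(), nn.Conv2D(in_ch, out_ch, 3, rng),
            nn.BatchNorm2D(out_ch), nn.ReLU(), nn.Conv2D(out_ch, out_ch, 3, rng),
        )
        self.project = None if in_ch == out_ch else nn.Conv2D(in_ch, out_ch, 1, rng)

    def params(self):
        ps = self.branch.params()
        if self.project is not None:
            ps += self.project.params()
        return ps

    def forward(self, x, train=True):
        y = self.branch.forward(x, train)
        skip = x if self.project is None else self.project.forward(x, train)
        return skip + y

    def backward(self, grad):
        gx = self.branch.backward(grad)
        gskip = grad if self.project is None else self.project.backward(grad)
        return gx + gskip


class DenseBlock(nn.Layer):
    """l dense layers of growth k; emits l*k channels (inputs dropped),
    then a 1x1 transition restores ``out_ch``."""

    def __init__(self, in_ch: int, out_ch: int, layers: int, growth: int, rng):
        self.layers = []
        ch = in_ch
        for _ in range(layers):
            self.layers.append(nn.Sequential(
                nn.BatchNorm2D(ch), nn.ReLU(), nn.Conv2D(ch, growth, 3, rng)))
            ch += growth
        self.n_in = in_ch
        self.growth = growth
        self.transition = nn.Conv2D(layers * growth, out_ch, 1, rng)

    def params(self):
        return [p for l in self.layers for p in l.params()] + self.transition.params()

    def forward(self, x, train=True):
        feats = [x]
        outs = []
        for layer in self.layers:
            cat = np.concatenate(feats, axis=1)
            y = layer.forward(cat, train)
            feats.append(y)
            outs.append(y)
        self._n_feats = [f.shape[1] for f in feats]
        block = np.concatenate(outs, axis=1)
        return self.transition.forward(block, train)

    def backward(self, grad):
        gblock = self.transition.backward(grad)
        k = self.growth
        L = len(self.layers)
        # gradient w.r.t. each dense layer's output from the block concat;
        # later layers feed gradient back into earlier outputs through
        # their input concatenations, so walk the layers in reverse.
        gout = [gblock[:, i * k : (i + 1) * k].copy() for i in range(L)]
        gfeat0 = None
        for j in reversed(range(L)):
            gcat = self.layers[j].backward(gout[j])
            off = 0
            for i, ni in enumerate(self._n_feats[: j + 1]):
                piece = gcat[:, off : off + ni]
                if i == 0:
                    gfeat0 = piece if gfeat0 is None else gfeat0 + piece
                else:
                    gout[i - 1] += piece  # feats[i] is the output of layer i-1
                off += ni
        return gfeat0


class _UNet(nn.Layer):
    """Shared encoder-decoder scaffold; the block factory sets the variant."""

    def __init__(self, spec: NetworkSpec, rng):
        self.spec = spec
        b, d = spec.base_channels, spec.depth
        mk = self._block_factory(spec, rng)
        self.enc = [mk(1 if l == 0 else b * 2 ** (l - 1), b * 2**l) for l in range(d)]
        self.pools = [nn.MaxPool2x2() for _ in range(d)]
        self.bottleneck = mk(b * 2 ** (d - 1), b * 2**d)
        self.ups, self.halves, self.dec = [], [], []
        for l in reversed(range(d)):
            ch = b * 2 ** (l + 1)
            self.ups.append(nn.ConvTranspose2x2(ch, ch, rng))
            self.halves.append(nn.Conv2D(ch, ch // 2, 3, rng))
            self.dec.append(mk(ch, b * 2**l))  # ch//2 (up) + ch//2 (skip)
        self.head = nn.Conv2D(b, 1, 1, rng)
        self.squash = nn.Sigmoid()

    @staticmethod
    def _block_factory(spec, rng):
        if spec.variant == "unet":
            return lambda i, o: nn.Sequential(conv_unit(i, o, rng), conv_unit(o, o, rng))
        if spec.variant == "residual":
            return lambda i, o: ResidualBlock(i, o, rng)
        return lambda i, o: DenseBlock(i, o, spec.dense_layers_per_block,
                                       spec.growth_rate, rng)

    def params(self):
        ps = []
        for group in (self.enc, [self.bottleneck], self.ups, self.halves, self.dec,
                      [self.head]):
            for l in group:
                ps += l.params()
        return ps

    def forward(self, x, train=True):
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_ch = []
        for up, half, blk, skip in zip(self.ups, self.halves, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = half.forward(x, train)
            self._skip_ch.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = blk.forward(x, train)
        x = self.head.forward(x, train)
        return self.squash.forward(x, train)

    def backward(self, grad):
        grad = self.squash.backward(grad)
        grad = self.head.backward(grad)
        skip_grads = []
        # walk the decoder in reverse construction order
        for up, half, blk, (ch_up, ch_skip) in zip(
            self.ups[::-1], self.halves[::-1], self.dec[::-1], self._skip_ch[::-1]
        ):
            g = blk.backward(grad)
            g_up, g_skip = g[:, :ch_up], g[:, ch_up:]
            skip_grads.append(g_skip)
            g = half.backward(g_up)
            grad = up.backward(g)
        grad = self.bottleneck.backward(grad)
        # skip_grads were collected top-level-first; encoder walks deepest-first
        for blk, pool, g_skip in zip(self.enc[::-1], self.pools[::-1], skip_grads[::-1]):
            grad = pool.backward(grad)
            grad = blk.backward(grad + g_skip)
        return grad


def build_network(spec: NetworkSpec, seed: int = 0) -> _UNet:
    """Instantiate a variant with seeded random initialisation."""
    return _UNet(spec, np.random.default_rng(seed))


def l2_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared difference between prediction and ground truth."""
    return nn.mse_loss(np.asarray(pred, dtype=float), np.asarray(truth, dtype=float))


def _to_batch(chips: list[np.ndarray]) -> np.ndarray:
    arr = np.stack([np.asarray(c, dtype=np.float32) for c in chips])
    return arr[:, None] / 255.0


def predict_proba(network: _UNet, chip: np.ndarray) -> np.ndarray:
    """Probability map in [0, 1] for a single chip."""
    h, w = network.spec.input_shape
    chip = np.asarray(chip)
    if chip.shape != (h, w):
        raise ValueError(f"chip shape {chip.shape} != network input {(h, w)}")
    return network.forward(_to_batch([chip]), train=False)[0, 0]


def predict_mask(network: _UNet, chip: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask from the thresholded probability map (p > threshold)."""
    return predict_proba(network, chip) > threshold


def augment(chips, masks, target: int, rng: np.random.Generator,
            config: TrainingConfig | None = None):
    """Inflate a chip/mask set to ``target`` pairs by jitter.

    Random small rotation, translation and intensity scaling; masks get
    the same geometric transform (nearest-neighbour) and stay binary.
    Original pairs are kept first, then jittered copies of random
    originals fill up to the target.
    """
    config = config or TrainingConfig()
    out_c = [np.asarray(c, dtype=np.float32) for c in chips]
    out_m = [np.asarray(m).astype(bool) for m in masks]
    while len(out_c) < target:
        i = int(rng.integers(len(chips)))
        c = np.asarray(chips[i], dtype=float)
        m = np.asarray(masks[i], dtype=float)
        ang = rng.uniform(-config.rotation_deg, config.rotation_deg)
        dr = rng.uniform(-config.translation_px, config.translation_px)
        dc = rng.uniform(-config.translation_px, config.translation_px)
        gain = rng.uniform(*config.intensity_scale)
        c2 = ndi.rotate(c, ang, reshape=False, order=1, mode="nearest")
        c2 = ndi.shift(c2, (dr, dc), order=1, mode="nearest") * gain
        m2 = ndi.rotate(m, ang, reshape=False, order=0, mode="constant")
        m2 = ndi.shift(m2, (dr, dc), order=0, mode="constant") > 0.5
        out_c.append(np.clip(c2, 0, 255).astype(np.float32))
        out_m.append(m2)
    return out_c[:target], out_m[:target]


def train(network: _UNet, chips, masks, config: TrainingConfig | None = None,
          augment_data: bool = True):
    """Fit a network on chip/mask pairs; returns per-epoch loss history.

    The training set is augmented to ``config.augmentation_target`` pairs
    and 10% of the augmented set is held out for validation.  Seeded and
    reproducible in single-threaded execution.
    """
    config = config or TrainingConfig()
    if len(chips) < 1:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(config.seed)
    if augment_data and len(chips) < config.augmentation_target:
        chips, masks = augment(chips, masks, config.augmentation_target, rng, config)
    x = _to_batch(list(chips))
    y = np.stack([np.asarray(m, dtype=np.float32) for m in masks])[:, None]
    n = len(x)
    n_val = int(round(config.validation_fraction * n))
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    opt = nn.Adam(network.params(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        perm = rng.permutation(tr_idx)
        losses = []
        for k in range(0, len(perm), config.batch_size):
            idx = perm[k : k + config.batch_size]
            opt.zero_grad()
            pred = network.forward(x[idx], train=True)
            loss = nn.mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}"
                )
            network.backward(nn.mse_grad(pred, y[idx]))
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if n_val:
            vl = []
            for k in range(0, n_val, config.batch_size):
                idx = val_idx[k : k + config.batch_size]
                vl.append(nn.mse_loss(network.forward(x[idx], train=False), y[idx]))
            history["val_loss"].append(float(np.mean(vl)))
    return network, history


def crossvalidate(dataset, spec: NetworkSpec, config: TrainingConfig | None = None):
    """k-fold cross-validation with image-level fold assignment.

    ``dataset`` is a list of images, each a list of (chip, mask) pairs;
    folds split whole images so chips from one radiograph never appear
    in both train and test.  Returns per-fold mean/sd DSC and the pooled
    mean/sd across all test chips.
    """
    config = config or TrainingConfig()
    k = config.folds
    if len(dataset) < k:
        raise ValueError(f"{len(dataset)} images cannot fill {k} folds")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    folds = np.array_split(order, k)
    fold_stats = []
    all_dsc = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        tr_chips, tr_masks = [], []
        for i in train_idx:
            for c, m in dataset[i]:
                tr_chips.append(c)
                tr_masks.append(m)
        net = build_network(spec, seed=config.seed + fi)
        cfg = replace(config, seed=config.seed + 1000 + fi)
        net, _ = train(net, tr_chips, tr_masks, cfg)
        dscs = []
        for i in test_idx:
            for c, m in dataset[i]:
                pred = predict_mask(net, c)
                dscs.append(evaluate(np.asarray(m, bool), pred).dsc)
        fold_stats.append((float(np.mean(dscs)), float(np.std(dscs))))
        all_dsc.extend(dscs)
    return {
        "per_fold": fold_stats,
        "mean": float(np.mean(all_dsc)),
        "sd": float(np.std(all_dsc)),
    }


def classical_segment(chip: np.ndarray) -> np.ndarray:
    """Training-free vertebra segmentation of a chip.

    Otsu global threshold, restricted to connected components that reach
    the chip's central band (neighbouring vertebrae intrude at the top
    and bottom edges), holes filled, largest qualifying component kept.
    """
    chip = np.asarray(chip, dtype=float)
    if chip.max() - chip.min() < 1e-6:
        warnings.warn("flat chip; returning empty mask")
        return np.zeros(chip.shape, dtype=bool)
    thr = threshold_otsu(chip)
    fg = chip > thr
    if not fg.any():
        warnings.warn("no foreground above the Otsu threshold")
        return fg
    labels, n = ndi.label(fg)
    if n == 0:
        warnings.warn("no connected components in the foreground")
        return np.zeros(chip.shape, dtype=bool)
    h, w = chip.shape
    centre = labels[int(0.3 * h) : int(0.7 * h), int(0.25 * w) : int(0.75 * w)]
    candidates = np.unique(centre[centre > 0])
    if len(candidates) == 0:
        warnings.warn("no component reaches the chip centre; returning empty mask")
        return np.zeros(chip.shape, dtype=bool)
    sizes = ndi.sum_labels(fg, labels, candidates)
    best = candidates[int(np.argmax(sizes))]
    mask = labels == best
    return ndi.binary_fill_holes(mask)
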