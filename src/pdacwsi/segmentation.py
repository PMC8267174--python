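"""U-Net tumor segmentation on 256 px half-overlap tiles.

The network is the classic encoder/decoder with skip connections, using
'same' convolutions so the output probability map has exactly the input's
spatial size (which is what makes half-overlap stitching line up). Training
minimises 1 - dice with a smoothing epsilon of 1.0; reported evaluation
dice uses epsilon 0. Augmentation is random horizontal flips plus a
per-channel brightness jitter of +/-10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn

TRAIN_EPS = 1.0


@dataclass
class SegmentationConfig:
    depth: int = 4
    base_filters: int = 64
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0
    augment: bool = True
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")

    @classmethod
    def test_preset(cls, **overrides) -> "SegmentationConfig":
        """A small configuration that trains in minutes on one CPU."""
        defaults = dict(depth=2, base_filters=8, epochs=5)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class DiceScore:
    value: float
    epsilon: float


def dice_coefficient(pred: np.ndarray, truth: np.ndarray,
                     epsilon: float = 0.0) -> DiceScore:
    """Soft dice (2|A.B| + eps) / (|A| + |B| + eps).

    pred is a probability mask in [0,1]; truth is binary. Two empty masks
    agree perfectly (dice 1) even at eps = 0.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("pred must lie in [0, 1]")
    if not np.isin(truth, (0.0, 1.0)).all():
        raise ValueError("truth must be binary")
    denom = pred.sum() + truth.sum() + epsilon
    if denom == 0:
        return DiceScore(value=1.0, epsilon=epsilon)
    return DiceScore(value=float((2.0 * (pred * truth).sum() + epsilon) / denom),
                     epsilon=epsilon)


def _dice_terms(p: np.ndarray, t: np.ndarray, epsilon: float):
    inter = (p * t).sum(axis=1)
    sums = p.sum(axis=1) + t.sum(axis=1) + epsilon
    dice = (2.0 * inter + epsilon) / sums
    # d(1 - dice_k)/dp_i = -(2 t_i * sums_k - (2 inter_k + eps)) / sums_k^2
    grad = -(2.0 * t * sums[:, None] - (2.0 * inter + epsilon)[:, None]) / (sums ** 2)[:, None]
    return dice, grad


def dice_loss_grad(pred: np.ndarray, truth: np.ndarray,
                   epsilon: float = TRAIN_EPS, symmetric: bool = True):
    """Mean (over batch) dice loss and its gradient w.r.t. pred,
    shapes (N, H, W).

    With ``symmetric`` the loss averages the tumor-channel dice and the
    background-channel dice (the two-class form): a constant all-tumor
    prediction then scores zero on the background term, which removes the
    degenerate optimum that plain single-channel soft dice has on
    majority-foreground masks. Reported evaluation dice stays the plain
    tumor-mask statistic.
    """
    n = pred.shape[0]
    p = pred.reshape(n, -1)
    t = truth.reshape(n, -1)
    dice_fg, grad_fg = _dice_terms(p, t, epsilon)
    if not symmetric:
        loss = float((1.0 - dice_fg).mean())
        return loss, (grad_fg / n).reshape(pred.shape)
    dice_bg, grad_bg = _dice_terms(1.0 - p, 1.0 - t, epsilon)
    loss = float((1.0 - 0.5 * (dice_fg + dice_bg)).mean())
    grad = 0.5 * (grad_fg - grad_bg)
    return loss, (grad / n).reshape(pred.shape)


def _run(layers, x):
    for layer in layers:
        x = layer.forward(x)
    return x


def _back(layers, d):
    for layer in reversed(layers):
        d = layer.backward(d)
    return d


class UNet:
    """Encoder/decoder with skip connections; sigmoid single-channel
    output the same spatial size as the input."""

    def __init__(self, config: SegmentationConfig, in_channels: int = 3) -> None:
        rng = np.random.Generator(np.random.PCG64(config.seed))
        self.config = config
        depth, base = config.depth, config.base_filters
        self.enc, self.pools = [], []
        c_in = in_channels
        for d in range(depth):
            c = base * 2 ** d
            self.enc.append([nn.Conv2D(c_in, c, rng), nn.ReLU(),
                             nn.Conv2D(c, c, rng), nn.ReLU()])
            self.pools.append(nn.MaxPool(2))
            c_in = c
        cb = base * 2 ** depth
        self.bottleneck = [nn.Conv2D(c_in, cb, rng), nn.ReLU(),
                           nn.Conv2D(cb, cb, rng), nn.ReLU()]
        self.dec = []
        c_in = cb
        for d in reversed(range(depth)):
            c = base * 2 ** d
            up = [nn.Upsample2x(), nn.Conv2D(c_in, c, rng), nn.ReLU()]
            conv = [nn.Conv2D(2 * c, c, rng), nn.ReLU(),
                    nn.Conv2D(c, c, rng), nn.ReLU()]
            self.dec.append((up, conv, c))
            c_in = c
        self.final = nn.Conv2D(c_in, 1, rng, k=1)
        self.sigmoid = nn.Sigmoid()

    def _all_layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.bottleneck
        for up, conv, _ in self.dec:
            yield from up
            yield from conv
        yield self.final

    def parameters(self):
        for layer in self._all_layers():
            for name in sorted(layer.params):
                yield layer, name

    def n_parameters(self) -> int:
        return sum(p.size for l in self._all_layers() for p in l.params.values())

    def state_dict(self):
        import copy
        return [copy.deepcopy(l.params) for l in self._all_layers()]

    def load_state_dict(self, state) -> None:
        import copy
        for layer, params in zip(self._all_layers(), state, strict=True):
            layer.params = copy.deepcopy(params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = _run(blk, x)
            skips.append(x)
            x = pool.forward(x)
        x = _run(self.bottleneck, x)
        for i, (up, conv, c) in enumerate(self.dec):
            x = _run(up, x)
            skip = skips[len(self.enc) - 1 - i]
            x = np.concatenate([x, skip], axis=-1)
            x = _run(conv, x)
        logits = self.final.forward(x)
        return self.sigmoid.forward(logits)[..., 0]

    def backward(self, dout: np.ndarray) -> None:
        d = self.sigmoid.backward(dout[..., None])
        d = self.final.backward(d)
        depth = len(self.enc)
        dskips = [None] * depth
        for i in reversed(range(len(self.dec))):
            up, conv, c = self.dec[i]
            d = _back(conv, d)
            dup, dskip = d[..., :c], d[..., c:]
            dskips[depth - 1 - i] = dskip
            d = _back(up, dup)
        d = _back(self.bottleneck, d)
        for level in reversed(range(depth)):
            d = self.pools[level].backward(d)
            d = d + dskips[level]
            d = _back(self.enc[level], d)


def _normalize(tiles: np.ndarray) -> np.ndarray:
    return tiles.astype(np.float32) / 127.5 - 1.0


def _jitter(batch: np.ndarray, masks: np.ndarray,
            rng: np.random.Generator):
    """Random horizontal flip (applied to image and mask alike) plus a
    per-channel brightness scale U(0.9, 1.1) on the [0, 1] intensity
    scale (image only)."""
    out = batch.copy()
    m = masks.copy()
    flips = rng.random(len(out)) < 0.5
    out[flips] = out[flips, :, ::-1]
    m[flips] = m[flips, :, ::-1]
    scale = rng.uniform(0.9, 1.1, size=(len(out), 1, 1, out.shape[-1])).astype(np.float32)
    return np.clip((out + 1.0) * scale - 1.0, -1.0, 1.0), m


@dataclass
class TrainedSegmenter:
    net: UNet
    log: pd.DataFrame = field(repr=False, default=None)
    best_epoch: int | None = None
    best_val_dice: float | None = None

    def predict(self, tiles, batch: int = 4) -> np.ndarray:
        """Probability maps, one per tile, same spatial size as the input."""
        X = _normalize(np.asarray(tiles)) if np.asarray(tiles).dtype == np.uint8 \
            else np.asarray(tiles, dtype=np.float32)
        outs = [self.net.forward(X[i:i + batch]) for i in range(0, len(X), batch)]
        return np.concatenate(outs, axis=0)


def train_unet(tiles, masks, config: SegmentationConfig) -> TrainedSegmenter:
    """Train on aligned (tile, mask) pairs; returns the checkpoint with the
    best validation dice. Fails if no mask contains a positive pixel."""
    tiles = np.asarray(tiles)
    masks = np.asarray(masks, dtype=np.float32)
    if tiles.shape[:3] != masks.shape[:3]:
        raise ValueError("tiles and masks must align")
    if masks.sum() == 0:
        raise ValueError("no positive pixels in any mask; nothing to segment")
    rng = np.random.Generator(np.random.PCG64(config.seed + 1))
    n = len(tiles)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    X = _normalize(tiles)
    Xtr, ytr = X[tr_idx], masks[tr_idx]
    Xval, yval = X[val_idx], masks[val_idx]

    net = UNet(config)
    opt = nn.Adam(net.parameters(), lr=config.learning_rate)
    rows = []
    best = (-1.0, -1, None)
    for epoch in range(config.epochs):
        perm = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start:start + config.batch_size]
            if config.augment:
                xb, yb = _jitter(Xtr[idx], ytr[idx], rng)
            else:
                xb, yb = Xtr[idx], ytr[idx]
            pred = net.forward(xb)
            loss, grad = dice_loss_grad(pred, yb)
            net.backward(grad)
            opt.step()
            losses.append(loss)
        seg = TrainedSegmenter(net=net)
        val_pred = seg.predict(Xval)
        val_dice = float(np.mean([
            dice_coefficient(val_pred[i], yval[i], epsilon=TRAIN_EPS).value
            for i in range(len(yval))]))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_dice": val_dice})
        if val_dice > best[0]:
            best = (val_dice, epoch, net.state_dict())
    if best[1] >= 0:
        net.load_state_dict(best[2])
    return TrainedSegmenter(net=net, log=pd.DataFrame(rows),
                            best_epoch=best[1], best_val_dice=best[0])


def stitch(tile_maps, offsets, canvas_size: tuple[int, int]) -> np.ndarray:
    """Average overlapping tile probability maps onto a canvas.

    Each output pixel is the mean of every tile prediction covering it;
    tile regions that overhang the canvas (the reflection-padded edge
    tiles) are cropped before averaging. Raises if any canvas pixel is
    uncovered.
    """
    h, w = canvas_size
    total = np.zeros((h, w), dtype=float)
    count = np.zeros((h, w), dtype=int)
    for tile, (x, y) in zip(tile_maps, offsets, strict=True):
        th, tw = tile.shape[:2]
        eh, ew = min(th, h - y), min(tw, w - x)
        if eh <= 0 or ew <= 0:
            continue
        total[y:y + eh, x:x + ew] += tile[:eh, :ew]
        count[y:y + eh, x:x + ew] += 1
    if (count == 0).any():
        bad = np.argwhere(count == 0)
        raise ValueError(f"uncovered canvas pixels, first at {tuple(bad[0])}")
    return total / count
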