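"""U-Net segmentation of calcified regions with per-artery classes.

Standard encoder-decoder with skip connections: each encoder level doubles
the filter count (so depth 4 starting at 64 filters gives a 1024-channel
bottleneck), the decoder mirrors it with nearest-neighbour upsampling and
skip concatenation, and a 1x1 projection emits 5 class logits (background +
RCA/LAD/LCA/LCX).  Training minimizes plain per-pixel cross-entropy with
Adam; the checkpoint with the best validation foreground Dice is kept.

Defaults are the full-scale configuration (64 initial filters, 512^2
inputs, lr 1e-4, batch 64, 100 epochs); desk-scale work uses
:meth:`UNetConfig.desk`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .ct_io import AnnotationMask, VALID_LABELS
from .nn import Tensor

__all__ = ["UNetConfig", "UNet", "build_unet", "train_unet", "segment_slices",
           "UNetSegmenter"]


@dataclass
class UNetConfig:
    initial_filters: int = 64
    depth: int = 4
    in_channels: int = 1
    out_classes: int = 5
    image_size: int = 512
    lr: float = 1e-4
    batch_size: int = 64
    epochs: int = 100

    def __post_init__(self):
        if self.image_size % (2 ** self.depth):
            raise ValueError(f"image_size {self.image_size} must be divisible by "
                             f"2^depth = {2 ** self.depth}")

    @staticmethod
    def desk(image_size: int = 64) -> "UNetConfig":
        """CPU-sized profile: same code path, far fewer filters and epochs."""
        return UNetConfig(initial_filters=8, depth=2, image_size=image_size,
                          lr=1e-3, batch_size=8, epochs=8)


class _DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x).relu()).relu()


class UNet(nn.Module):
    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        f = config.initial_filters
        chans = [config.in_channels] + [f * 2 ** i for i in range(config.depth)]
        self.enc = [_DoubleConv(chans[i], chans[i + 1], rng)
                    for i in range(config.depth)]
        self.bottleneck = _DoubleConv(chans[-1], f * 2 ** config.depth, rng)
        self.dec = []
        up_in = f * 2 ** config.depth
        for i in reversed(range(config.depth)):
            skip = chans[i + 1]
            self.dec.append(_DoubleConv(up_in + skip, skip, rng))
            up_in = skip
        self.final = nn.Conv2d(f, config.out_classes, 1, rng)

    @property
    def bottleneck_channels(self) -> int:
        return self.config.initial_filters * 2 ** self.config.depth

    def forward(self, x) -> Tensor:
        x = nn.as_tensor(x)
        skips = []
        for enc in self.enc:
            x = enc(x)
            skips.append(x)
            x = nn.max_pool2d(x, 2)
        x = self.bottleneck(x)
        for dec, skip in zip(self.dec, reversed(skips)):
            x = nn.upsample_nearest2x(x)
            x = dec(nn.concat([x, skip], axis=1))
        return self.final(x)


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    return UNet(config, np.random.default_rng(seed))


def _pixel_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    B, K, H, W = logits.shape
    flat = logits.transpose(0, 2, 3, 1).reshape(B * H * W, K)
    y = np.asarray(labels).reshape(-1).astype(int)
    logp = flat.log_softmax(axis=-1)
    return -(logp[np.arange(y.size), y].mean())


def _foreground_dice(pred: np.ndarray, true: np.ndarray,
                     n_classes: int = 5) -> float:
    """Mean Dice over foreground classes present in either mask.

    Undefined (NaN) when the reference contains no foreground at all."""
    if not (np.asarray(true) > 0).any():
        return float("nan")
    vals = []
    for c in range(1, n_classes):
        p = pred == c
        t = true == c
        denom = p.sum() + t.sum()
        if denom == 0:
            continue
        vals.append(2.0 * (p & t).sum() / denom)
    return float(np.mean(vals)) if vals else float("nan")


def train_unet(slices, masks, config: UNetConfig | None = None, seed: int = 0,
               val_slices=None, val_masks=None, steps: int | None = None):
    """Train a U-Net on normalized slices and integer label masks.

    ``steps`` optionally caps the total number of optimizer steps (used by
    quick overfitting checks); otherwise ``config.epochs`` full passes run.
    The parameters from the epoch with the best validation foreground Dice
    are restored; without a validation set the training set is used for
    checkpoint selection.
    """
    cfg = config or UNetConfig()
    X = np.asarray(slices, dtype=np.float32)
    Y = np.asarray(masks)
    if X.ndim != 3 or Y.shape != X.shape:
        raise ValueError("need aligned (N, H, W) slices and masks")
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    bad = set(np.unique(Y)) - VALID_LABELS
    if bad:
        raise ValueError(f"masks contain labels outside 0..4: {sorted(bad)}")
    if not Y.any():
        warnings.warn("all-background masks: foreground Dice is undefined for "
                      "this training set")
    if val_slices is None:
        Xv, Yv = X, Y
    else:
        Xv = np.asarray(val_slices, dtype=np.float32)
        Yv = np.asarray(val_masks)

    rng = np.random.default_rng(seed)
    net = UNet(cfg, rng)
    opt = nn.Adam(net.parameters(), lr=cfg.lr)
    history = {"epoch": [], "loss": [], "val_dice": [], "step_loss": []}
    best = {"dice": -np.inf, "state": net.state_dict(), "epoch": -1}
    n = X.shape[0]
    total_steps = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0:b0 + cfg.batch_size]
            logits = net(X[idx][:, None])
            loss = _pixel_cross_entropy(logits, Y[idx])
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            history["step_loss"].append(float(loss.data))
            total_steps += 1
            if steps is not None and total_steps >= steps:
                break
        pred = segment_slices(net, Xv).labels
        dice = _foreground_dice(pred, Yv, cfg.out_classes)
        history["epoch"].append(epoch)
        history["loss"].append(float(np.mean(losses)))
        history["val_dice"].append(dice)
        if np.isnan(dice):
            if best["epoch"] < 0:  # no usable checkpoint yet
                best = {"dice": dice, "state": net.state_dict(), "epoch": epoch}
        elif best["epoch"] < 0 or np.isnan(best["dice"]) or dice > best["dice"]:
            best = {"dice": dice, "state": net.state_dict(), "epoch": epoch}
        if steps is not None and total_steps >= steps:
            break
    net.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    history["best_dice"] = best["dice"]
    return net, history


def segment_slices(net: UNet, slices) -> AnnotationMask:
    """Per-pixel argmax labels; ties resolve to the lowest class index."""
    X = np.asarray(slices, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    if X.shape[0] == 0:
        return AnnotationMask(labels=np.zeros((0,) + X.shape[1:], dtype=np.uint8))
    out = []
    bs = max(1, min(8, X.shape[0]))
    for b0 in range(0, X.shape[0], bs):
        with nn.no_grad():
            logits = net(X[b0:b0 + bs][:, None]).data
        out.append(np.argmax(logits, axis=1).astype(np.uint8))
    return AnnotationMask(labels=np.concatenate(out, axis=0))


from sklearn.base import BaseEstimator


class UNetSegmenter(BaseEstimator):
    """Scikit-learn-style wrapper: fit on (N, H, W) slices + masks, predict
    label volumes.  Fitted attributes: ``net_``, ``history_``."""

    def __init__(self, initial_filters: int = 8, depth: int = 2,
                 image_size: int = 64, lr: float = 1e-3, batch_size: int = 8,
                 epochs: int = 8, seed: int = 0):
        self.initial_filters = initial_filters
        self.depth = depth
        self.image_size = image_size
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _config(self) -> UNetConfig:
        return UNetConfig(initial_filters=self.initial_filters, depth=self.depth,
                          image_size=self.image_size, lr=self.lr,
                          batch_size=self.batch_size, epochs=self.epochs)

    def fit(self, X, y, X_val=None, y_val=None):
        self.net_, self.history_ = train_unet(X, y, config=self._config(),
                                              seed=self.seed, val_slices=X_val,
                                              val_masks=y_val)
        return self

    def predict(self, X) -> np.ndarray:
        return segment_slices(self.net_, X).labels
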