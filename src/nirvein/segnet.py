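"""U-Net with a ResNet18 encoder, BYOL pretraining and transfer.

The segmentation network keeps the U-Net decoder and skip connections
but replaces the encoder with the ResNet18 layout: a 7x7/2 stem and
four stages of two residual basic blocks (channels 64/64/128/256/512,
scaled by a width multiplier so a desk-scale profile trains on one
CPU).  Each decoder stage doubles resolution, concatenates the matching
encoder feature map, and applies two 3x3 conv+BN+ReLU layers; a 1x1
conv + sigmoid head yields per-pixel vein probabilities.

The encoder can first be pretrained on unlabeled images with BYOL: an
online network (encoder + projector + predictor) learns to predict the
projection of a second augmented view produced by a target network
whose weights are an exponential moving average of the online weights.
The symmetrized loss per view pair is

    L = 2 - 2 * cos(q(v1), z'(v2))  averaged over both view orderings,

bounded in [0, 4].  Pretrained encoder parameters are transferred into
the segmentation network and all layers are fine-tuned with mean
binary cross-entropy on labeled masks.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize

from . import metrics as M
from .nn import (
    F32,
    Adam,
    BatchNorm1d,
    BatchNorm2d,
    Conv2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    UpsampleNearest2,
    sigmoid,
)

__all__ = [
    "NetConfig",
    "ByolConfig",
    "FinetuneConfig",
    "TrainState",
    "build_network",
    "byol_pretrain",
    "transfer_and_finetune",
    "segment",
    "save_checkpoint",
    "load_checkpoint",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- configs


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters.

    ``width_multiplier`` scales every channel count; 1.0 is the full
    ResNet18 width (64/64/128/256/512), 0.25 the desk-scale profile
    used throughout the tests.  ``input_size`` must be a multiple of 32
    (five halvings in the encoder).
    """

    in_channels: int = 1
    input_size: int = 96
    width_multiplier: float = 0.25

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0:
            raise ValueError(f"input_size must be a multiple of 32, got {self.input_size}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    @property
    def base_channels(self) -> int:
        return max(4, int(round(64 * self.width_multiplier)))


@dataclass(frozen=True)
class ByolConfig:
    """BYOL pretraining schedule and augmentation magnitudes."""

    epochs: int = 50
    batch_size: int = 12
    lr: float = 2e-3
    ema_momentum: float = 0.95  # fast target for short CPU-scale runs
    projector_hidden: int = 128
    projector_dim: int = 64
    predictor_hidden: int = 128
    crop_scale: tuple[float, float] = (0.6, 1.0)
    flip_prob: float = 0.5
    jitter_prob: float = 0.8
    brightness: float = 0.2
    contrast: float = 0.2
    blur_prob: float = 0.2
    blur_sigma: tuple[float, float] = (0.5, 1.5)
    cosine_lr: bool = True  # decay lr to 0 over the run (reference schedule)
    warmup_epochs: int = 5  # linear lr warmup before the cosine decay
    predictor_lr_mult: float = 10.0  # extra lr factor on the predictor head
    ema_ramp: bool = False  # optionally ramp target momentum toward 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ema_momentum < 1.0):
            raise ValueError("EMA momentum must lie in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid schedule")


@dataclass(frozen=True)
class FinetuneConfig:
    epochs: int = 30
    batch_size: int = 5
    lr: float = 1e-3
    val_fraction: float = 0.25
    seed: int = 0
    net: NetConfig = field(default_factory=NetConfig)


@dataclass
class TrainState:
    """Per-epoch traces recorded during supervised fine-tuning."""

    epochs: int
    seed: int
    train_bce: list[float] = field(default_factory=list)
    train_bce_batch_sum: list[float] = field(default_factory=list)
    val_bce: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_hd: list[float] = field(default_factory=list)
    best_dice: float = -1.0
    best_epoch: int = -1
    checkpoint: dict | None = None


# ---------------------------------------------------------------- network


class BasicBlock(Module):
    """ResNet basic block: two 3x3 convs with an identity shortcut."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        self.has_down = stride != 1 or cin != cout
        if self.has_down:
            self.down_conv = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
            self.down_bn = BatchNorm2d(cout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        idt = self.down_bn.forward(self.down_conv.forward(x)) if self.has_down else x
        y = self.bn2.forward(self.conv2.forward(self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))))
        return self.relu2.forward(y + idt)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(g)
        t = self.bn2.backward(g)
        t = self.conv2.backward(t)
        t = self.relu1.backward(t)
        t = self.bn1.backward(t)
        t = self.conv1.backward(t)
        if self.has_down:
            t = t + self.down_conv.backward(self.down_bn.backward(g))
        else:
            t = t + g
        return t


class ResNet18Encoder(Module):
    """ResNet18 stem + 4 stages; exposes the five-skip feature pyramid."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.channels = [c, c, 2 * c, 4 * c, 8 * c]
        self.stem_conv = Conv2d(cfg.in_channels, c, 7, stride=2, pad=3, rng=rng)
        self.stem_bn = BatchNorm2d(c)
        self.stem_relu = ReLU()
        self.pool = MaxPool2d(3, 2, 1)
        self.layer1 = [BasicBlock(c, c, 1, rng), BasicBlock(c, c, 1, rng)]
        self.layer2 = [BasicBlock(c, 2 * c, 2, rng), BasicBlock(2 * c, 2 * c, 1, rng)]
        self.layer3 = [BasicBlock(2 * c, 4 * c, 2, rng), BasicBlock(4 * c, 4 * c, 1, rng)]
        self.layer4 = [BasicBlock(4 * c, 8 * c, 2, rng), BasicBlock(8 * c, 8 * c, 1, rng)]

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        f0 = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x)))
        y = self.pool.forward(f0)
        feats = [f0]
        for stage in (self.layer1, self.layer2, self.layer3, self.layer4):
            for block in stage:
                y = block.forward(y)
            feats.append(y)
        return feats  # resolutions H/2, H/4, H/8, H/16, H/32

    def backward(self, grads: list[np.ndarray | None]) -> np.ndarray:
        """Backprop given gradients for each pyramid level (None = unused)."""
        g0, g1, g2, g3, g4 = grads
        g = g4
        for stage, skip in (
            (self.layer4, g3),
            (self.layer3, g2),
            (self.layer2, g1),
        ):
            for block in reversed(stage):
                g = block.backward(g)
            if skip is not None:
                g = g + skip
        for block in reversed(self.layer1):
            g = block.backward(g)
        g = self.pool.backward(g)
        if g0 is not None:
            g = g + g0
        g = self.stem_relu.backward(g)
        g = self.stem_bn.backward(g)
        return self.stem_conv.backward(g)


def _conv_block(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng=rng), BatchNorm2d(cout), ReLU(),
        Conv2d(cout, cout, 3, rng=rng), BatchNorm2d(cout), ReLU(),
    )


class UNetResNet18(Module):
    """Segmentation network: ResNet18 encoder, U-Net decoder, sigmoid head."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.encoder = ResNet18Encoder(cfg, rng)
        c0, c1, c2, c3, c4 = self.encoder.channels
        self.up4, self.up3, self.up2, self.up1, self.up0 = (UpsampleNearest2() for _ in range(5))
        self.dec4 = _conv_block(c4 + c3, c3, rng)
        self.dec3 = _conv_block(c3 + c2, c2, rng)
        self.dec2 = _conv_block(c2 + c1, c1, rng)
        self.dec1 = _conv_block(c1 + c0, c0, rng)
        self.final = _conv_block(c0, c0, rng)
        self.head = Conv2d(c0, 1, 1, pad=0, rng=rng)
        self._splits: list[int] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map (N, C, H, W) to per-pixel probabilities of the same geometry."""
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input size must be a multiple of 32, got {h}x{w}")
        f0, f1, f2, f3, f4 = self.encoder.forward(x.astype(F32))
        self._splits = [f.shape[1] for f in (f3, f2, f1, f0)]
        d = self.dec4.forward(np.concatenate([self.up4.forward(f4), f3], axis=1))
        d = self.dec3.forward(np.concatenate([self.up3.forward(d), f2], axis=1))
        d = self.dec2.forward(np.concatenate([self.up2.forward(d), f1], axis=1))
        d = self.dec1.forward(np.concatenate([self.up1.forward(d), f0], axis=1))
        d = self.final.forward(self.up0.forward(d))
        self._logits = self.head.forward(d)
        return sigmoid(self._logits)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop from the gradient w.r.t. the pre-sigmoid logits."""
        g = self.head.backward(dlogits.astype(F32))
        g = self.up0.backward(self.final.backward(g))
        skips: list[np.ndarray] = []
        for dec, up, csplit in (
            (self.dec1, self.up1, self._splits[3]),
            (self.dec2, self.up2, self._splits[2]),
            (self.dec3, self.up3, self._splits[1]),
            (self.dec4, self.up4, self._splits[0]),
        ):
            g = dec.backward(g)
            g, gskip = g[:, :-csplit], g[:, -csplit:]
            skips.append(np.ascontiguousarray(gskip))
            g = up.backward(np.ascontiguousarray(g))
        g0, g1, g2, g3 = skips  # recorded shallow-to-deep? no: dec1 first -> g0 is f0 grad
        self.encoder.backward([g0, g1, g2, g3, g])

    def num_params(self) -> int:
        return sum(p.data.size for p in self.params())


def build_network(cfg: NetConfig | None = None, seed: int = 0) -> UNetResNet18:
    """Construct a randomly initialized U-Net+ResNet18."""
    cfg = cfg or NetConfig()
    return UNetResNet18(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------- BYOL


class _MLPHead(Module):
    def __init__(self, cin: int, hidden: int, cout: int, rng: np.random.Generator):
        self.net = Sequential(Linear(cin, hidden, rng), BatchNorm1d(hidden), ReLU(),
                              Linear(hidden, cout, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g)


class _ByolBranch(Module):
    """Encoder + global average pool + projector (+ optional predictor)."""

    def __init__(self, net_cfg: NetConfig, cfg: ByolConfig, rng: np.random.Generator):
        self.encoder = ResNet18Encoder(net_cfg, rng)
        feat = self.encoder.channels[-1]
        self.projector = _MLPHead(feat, cfg.projector_hidden, cfg.projector_dim, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = self.encoder.forward(x)
        self._f4_shape = feats[-1].shape
        pooled = feats[-1].mean(axis=(2, 3))
        return self.projector.forward(pooled)

    def backward(self, g: np.ndarray) -> None:
        g = self.projector.backward(g)
        n, c, h, w = self._f4_shape
        g4 = np.broadcast_to(g[:, :, None, None] / (h * w), (n, c, h, w)).astype(F32)
        self.encoder.backward([None, None, None, None, g4])


def _augment(img: np.ndarray, cfg: ByolConfig, rng: np.random.Generator) -> np.ndarray:
    """One random view: crop-resize, flip, brightness/contrast, blur."""
    h, w = img.shape
    out = img
    side = np.sqrt(rng.uniform(*cfg.crop_scale))
    ch, cw = max(8, int(round(h * side))), max(8, int(round(w * side)))
    if ch < h or cw < w:
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        out = sk_resize(out[r0 : r0 + ch, c0 : c0 + cw], (h, w), order=1,
                        anti_aliasing=False, preserve_range=True)
    if rng.random() < cfg.flip_prob:
        out = out[:, ::-1]
    if rng.random() < cfg.jitter_prob:
        out = out * rng.uniform(1 - cfg.contrast, 1 + cfg.contrast) + rng.uniform(
            -cfg.brightness, cfg.brightness
        )
    if rng.random() < cfg.blur_prob:
        out = ndimage.gaussian_filter(out, rng.uniform(*cfg.blur_sigma))
    return np.clip(out, 0.0, 1.0).astype(F32)


def byol_loss(q: np.ndarray, z: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean of 2 - 2*cos(q_i, z_i) and its gradient w.r.t. q.

    ``z`` is treated as a constant (stop-gradient on the target).
    """
    qn = np.linalg.norm(q, axis=1, keepdims=True).clip(min=1e-12)
    zn = np.linalg.norm(z, axis=1, keepdims=True).clip(min=1e-12)
    qh, zh = q / qn, z / zn
    cos = np.sum(qh * zh, axis=1)
    loss = float(np.mean(2.0 - 2.0 * cos))
    dq = (-2.0 / q.shape[0]) * (zh - cos[:, None] * qh) / qn
    return loss, dq.astype(F32)


def byol_pretrain(
    images: list[np.ndarray],
    cfg: ByolConfig | None = None,
    net_cfg: NetConfig | None = None,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Self-supervised encoder pretraining.

    Returns the final online-encoder state dict and the per-epoch mean
    symmetrized loss trace.
    """
    cfg = cfg or ByolConfig()
    net_cfg = net_cfg or NetConfig()
    if len(images) < 2:
        if len(images) == 1:
            warnings.warn("BYOL with a single image risks representation collapse")
        else:
            raise ValueError("BYOL pretraining needs at least one image")
    rng = np.random.default_rng(cfg.seed)
    online = _ByolBranch(net_cfg, cfg, rng)
    predictor = _MLPHead(cfg.projector_dim, cfg.predictor_hidden, cfg.projector_dim, rng)
    target = copy.deepcopy(online)

    opt = Adam(online.params(), lr=cfg.lr)
    opt_pred = Adam(predictor.params(), lr=cfg.lr * cfg.predictor_lr_mult)
    data = [np.asarray(im, dtype=F32) for im in images]
    trace: list[float] = []
    online_params = online.named_params()
    target_params = dict(target.named_params())
    for epoch in range(cfg.epochs):
        frac = epoch / max(cfg.epochs, 1)
        lr_factor = 0.5 * (1.0 + np.cos(np.pi * frac)) if cfg.cosine_lr else 1.0
        if epoch < cfg.warmup_epochs:
            lr_factor = (epoch + 1) / cfg.warmup_epochs
        opt.lr = cfg.lr * lr_factor
        opt_pred.lr = cfg.lr * cfg.predictor_lr_mult * lr_factor
        m = 1.0 - (1.0 - cfg.ema_momentum) * 0.5 * (1.0 + np.cos(np.pi * frac)) \
            if cfg.ema_ramp else cfg.ema_momentum
        order = rng.permutation(len(data))
        losses = []
        for start in range(0, len(data), cfg.batch_size):
            batch = [data[i] for i in order[start : start + cfg.batch_size]]
            v1 = np.stack([_augment(im, cfg, rng) for im in batch])[:, None]
            v2 = np.stack([_augment(im, cfg, rng) for im in batch])[:, None]
            # both orderings in one pass: online sees [v1; v2], target [v2; v1]
            x_on = np.concatenate([v1, v2])
            x_tg = np.concatenate([v2, v1])
            q = predictor.forward(online.forward(x_on))
            z = target.forward(x_tg)  # no gradient flows back through this
            loss, dq = byol_loss(q, z)
            online.zero_grad()
            predictor.zero_grad()
            online.backward(predictor.backward(dq))
            opt.step()
            opt_pred.step()
            for name, p in online_params:
                tp = target_params[name]
                tp.data *= m
                tp.data += (1.0 - m) * p.data
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        log.info("byol epoch %d/%d: loss %.4f", epoch + 1, cfg.epochs, trace[-1])
    return online.encoder.state_dict(), trace


# ---------------------------------------------------------- fine-tuning


def _eval_net(net: UNetResNet18, images: np.ndarray, masks: np.ndarray) -> dict[str, float]:
    net.set_train(False)
    probs = np.concatenate([net.forward(images[i : i + 4]) for i in range(0, len(images), 4)])
    net.set_train(True)
    probs = probs[:, 0]
    pred = probs >= 0.5
    counts = M.confusion(pred, masks.astype(bool))
    try:
        hd = float(np.mean([
            M.hausdorff_masks(pred[i], masks[i].astype(bool)) for i in range(len(masks))
        ]))
    except ValueError:
        hd = float("nan")  # empty prediction or label boundary
    return {
        "bce": M.bce(probs, masks),
        "iou": M.iou(counts),
        "dice": M.dice(counts),
        "hd": hd,
    }


def transfer_and_finetune(
    encoder_state: dict[str, np.ndarray] | None,
    labeled: list[tuple[np.ndarray, np.ndarray]],
    cfg: FinetuneConfig | None = None,
) -> tuple[UNetResNet18, TrainState]:
    """Supervised fine-tuning of the full network with mean BCE loss.

    ``encoder_state`` (from :func:`byol_pretrain`) initializes the
    encoder; ``None`` keeps the random initialization.  All layers stay
    trainable.  A held-out split is scored every epoch with BCE / IoU /
    Dice / HD, and the parameters with the best Dice are checkpointed.
    """
    cfg = cfg or FinetuneConfig()
    rng = np.random.default_rng(cfg.seed)
    net = UNetResNet18(cfg.net, rng)
    if encoder_state is not None:
        net.encoder.load_state_dict(encoder_state)

    imgs = np.stack([np.asarray(im, dtype=F32) for im, _ in labeled])[:, None]
    masks = np.stack([np.asarray(mk, dtype=F32) for _, mk in labeled])
    n = len(labeled)
    n_val = min(n - 1, max(1, int(round(cfg.val_fraction * n)))) if n > 1 else 0
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]

    opt = Adam(net.params(), lr=cfg.lr)
    state = TrainState(epochs=cfg.epochs, seed=cfg.seed)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(train_idx))
        batch_losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idx = train_idx[perm[start : start + cfg.batch_size]]
            x, y = imgs[idx], masks[idx][:, None]
            prob = net.forward(x)
            batch_losses.append(M.bce(prob[:, 0], y[:, 0]))
            net.zero_grad()
            net.backward((prob - y) / prob.size)  # BCE-through-sigmoid gradient
            opt.step()
        state.train_bce.append(float(np.mean(batch_losses)))
        state.train_bce_batch_sum.append(float(np.sum(batch_losses)))
        if n_val:
            scores = _eval_net(net, imgs[val_idx], masks[val_idx])
            state.val_bce.append(scores["bce"])
            state.val_iou.append(scores["iou"])
            state.val_dice.append(scores["dice"])
            state.val_hd.append(scores["hd"])
            if scores["dice"] > state.best_dice:
                state.best_dice = scores["dice"]
                state.best_epoch = epoch
                state.checkpoint = net.state_dict()
        log.info("finetune epoch %d/%d: bce %.4f", epoch + 1, cfg.epochs, state.train_bce[-1])
    if state.checkpoint is None:
        state.checkpoint = net.state_dict()
    return net, state


def segment(net: UNetResNet18, img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel vein probability and its 0.5-threshold mask.

    The image is reflect-padded to the next multiple of 32, run through
    the network in eval mode, and un-padded back to its own geometry.
    The mask uses the >= 0.5 convention, so a probability of exactly
    0.5 counts as foreground.
    """
    img = np.asarray(img, dtype=F32)
    h, w = img.shape
    ph = (-h) % 32
    pw = (-w) % 32
    padded = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else img
    net.set_train(False)
    prob = net.forward(padded[None, None])[0, 0]
    net.set_train(True)
    prob = prob[:h, :w]
    return prob, prob >= 0.5


# ---------------------------------------------------------- checkpoints


def save_checkpoint(path: str | Path, net: UNetResNet18) -> None:
    """Single-file checkpoint: parameters plus embedded architecture config."""
    cfg = json.dumps(asdict(net.cfg))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **net.state_dict())


def load_checkpoint(path: str | Path) -> UNetResNet18:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    net = UNetResNet18(NetConfig(**cfg_dict))
    net.load_state_dict(state)
    return net
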