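"""U-Net semantic segmentation with a weighted combined loss.

The network is the canonical encoder/decoder with skip connections: each
contracting block applies two 3x3 convolutions (ReLU) and a 2x2 max pool,
doubling the channel count per stage; the expansive path mirrors it with
2x2 transposed-convolution upsampling and concatenating skips.  A final 1x1
convolution maps to class logits, so output spatial size equals input size
(inputs are edge-padded to a multiple of ``2**depth`` internally and the
logits cropped back).  Dropout sits after each encoder block's second
convolution and is disabled at inference.

Training minimises a weighted combination of pixel cross-entropy and mean
squared error between predicted class probabilities and the one-hot target
(default weights 0.5 / 0.5, the published setting), both averaged under a
per-pixel weight map that up-weights hard pixels near instance boundaries.
The optimiser is plain SGD with an explicit L2 penalty on convolution
weights (default learning rate 0.001, 50 epochs, batch 16, L2 0.01,
dropout 0.5 — the published hyperparameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import HEImage, InstanceLabelMap
from . import nnet
from .nnet import Conv2d, ConvTranspose2x2, Dropout, MaxPool2x2, Param, ReLU, SGD

__all__ = [
    "UNetConfig", "LossConfig", "TrainConfig", "UNet",
    "build_unet", "combined_loss", "make_weight_map", "train",
    "predict_probmap", "validate_probmap",
]


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_channels: int = 16
    n_classes: int = 2
    in_channels: int = 3
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0.0 <= self.dropout_p <= 1.0):
            raise ValueError("dropout_p must lie in [0, 1]")


@dataclass(frozen=True)
class LossConfig:
    w_ce: float = 0.5
    w_mse: float = 0.5
    class_weights: tuple[float, ...] | None = None  # None -> inverse class frequency
    boundary_weight: float = 3.0
    boundary_radius: int = 2

    def __post_init__(self) -> None:
        if self.w_ce < 0 or self.w_mse < 0 or self.w_ce + self.w_mse <= 0:
            raise ValueError("loss weights must be >= 0 with a positive sum")
        if self.boundary_weight < 1:
            raise ValueError("boundary_weight must be >= 1")
        if self.class_weights is not None and min(self.class_weights) <= 0:
            raise ValueError("class weights must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 16
    l2_lambda: float = 0.01
    seed: int = 0
    max_steps: int | None = None  # optional cap on total SGD steps
    grad_clip: float | None = 1.0  # global gradient-norm ceiling

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0 or self.batch_size < 1 or self.l2_lambda < 0:
            raise ValueError("invalid training configuration")


class UNet:
    """Encoder/decoder segmentation network; see the module docstring."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        self.enc_convs: list[tuple[Conv2d, ReLU, Conv2d, ReLU, Dropout]] = []
        self.pools: list[MaxPool2x2] = []
        in_ch = config.in_channels
        for i in range(config.depth):
            ch = c * 2 ** i
            self.enc_convs.append((
                Conv2d(in_ch, ch, 3, rng), ReLU(),
                Conv2d(ch, ch, 3, rng), ReLU(),
                Dropout(config.dropout_p),
            ))
            self.pools.append(MaxPool2x2())
            in_ch = ch
        bch = c * 2 ** config.depth
        self.bott = (Conv2d(in_ch, bch, 3, rng), ReLU(), Conv2d(bch, bch, 3, rng), ReLU())
        self.ups: list[ConvTranspose2x2] = []
        self.dec_convs: list[tuple[Conv2d, ReLU, Conv2d, ReLU]] = []
        prev = bch
        for i in reversed(range(config.depth)):
            ch = c * 2 ** i
            self.ups.append(ConvTranspose2x2(prev, ch, rng))
            self.dec_convs.append((Conv2d(2 * ch, ch, 3, rng), ReLU(), Conv2d(ch, ch, 3, rng), ReLU()))
            prev = ch
        self.out_conv = Conv2d(prev, config.n_classes, 1, rng)
        self._pad = (0, 0)

    # -- parameter bookkeeping -------------------------------------------
    def named_params(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for i, (c1, _r1, c2, _r2, _d) in enumerate(self.enc_convs):
            out[f"enc{i}.c1.w"], out[f"enc{i}.c1.b"] = c1.w, c1.b
            out[f"enc{i}.c2.w"], out[f"enc{i}.c2.b"] = c2.w, c2.b
        out["bott.c1.w"], out["bott.c1.b"] = self.bott[0].w, self.bott[0].b
        out["bott.c2.w"], out["bott.c2.b"] = self.bott[2].w, self.bott[2].b
        for i, (up, (c1, _r1, c2, _r2)) in enumerate(zip(self.ups, self.dec_convs)):
            out[f"up{i}.w"], out[f"up{i}.b"] = up.w, up.b
            out[f"dec{i}.c1.w"], out[f"dec{i}.c1.b"] = c1.w, c1.b
            out[f"dec{i}.c2.w"], out[f"dec{i}.c2.b"] = c2.w, c2.b
        out["out.w"], out["out.b"] = self.out_conv.w, self.out_conv.b
        return out

    def params(self) -> list[Param]:
        return list(self.named_params().values())

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    @property
    def n_skip_connections(self) -> int:
        return self.config.depth

    def save(self, path) -> None:
        nnet.save_params(path, self.named_params())

    def load(self, path) -> None:
        nnet.load_params(path, self.named_params())

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """(N, C, H, W) -> logits (N, n_classes, H, W)."""
        n, _c, h, w = x.shape
        m = 2 ** self.config.depth
        ph, pw = (-h) % m, (-w) % m
        self._pad = (ph, pw)
        self._in_hw = (h, w)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        skips = []
        for (c1, r1, c2, r2, dp), pool in zip(self.enc_convs, self.pools):
            x = r2.forward(c2.forward(r1.forward(c1.forward(x))))
            x = dp.forward(x, train, rng)
            skips.append(x)
            x = pool.forward(x)
        c1, r1, c2, r2 = self.bott
        x = r2.forward(c2.forward(r1.forward(c1.forward(x))))
        self._skip_channels = []
        for up, (d1, r1_, d2, r2_), skip in zip(self.ups, self.dec_convs, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = r2_.forward(d2.forward(r1_.forward(d1.forward(x))))
        logits = self.out_conv.forward(x)
        return logits[:, :, :h, :w]

    def backward(self, dlogits: np.ndarray) -> None:
        h, w = self._in_hw
        ph, pw = self._pad
        if ph or pw:
            full = np.zeros(dlogits.shape[:2] + (h + ph, w + pw), dtype=dlogits.dtype)
            full[:, :, :h, :w] = dlogits
            dlogits = full
        dx = self.out_conv.backward(dlogits)
        dskips: list[np.ndarray] = []
        for (d1, r1_, d2, r2_), up, sc in zip(
            reversed(self.dec_convs), reversed(self.ups), reversed(self._skip_channels)
        ):
            dx = d1.backward(r1_.backward(d2.backward(r2_.backward(dx))))
            dskip, dup = dx[:, :sc], dx[:, sc:]
            dskips.append(dskip)
            dx = up.backward(dup)
        c1, r1, c2, r2 = self.bott
        dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))
        # dskips[k] holds the decoder's gradient for encoder stage k's output
        for (c1_, r1_, c2_, r2_, dp), pool, dskip in zip(
            reversed(self.enc_convs), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dx) + dskip
            dy = dp.backward(dy)
            dx = c1_.backward(r1_.backward(c2_.backward(r2_.backward(dy))))


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    return UNet(config, seed=seed)


def validate_probmap(probs: np.ndarray, atol: float = 1e-5) -> None:
    if probs.ndim != 3:
        raise ValueError("probability map must be HxWxC")
    if probs.min() < -atol or probs.max() > 1 + atol:
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.allclose(probs.sum(axis=2), 1.0, atol=atol):
        raise ValueError("per-pixel class probabilities must sum to 1")


def make_weight_map(labels: InstanceLabelMap | np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Per-pixel loss weights: class weight times ``boundary_weight`` within
    ``boundary_radius`` (Chebyshev) of an instance boundary.

    A boundary pixel is a foreground pixel 8-adjacent to a different label
    (background included).  With ``class_weights=None`` the class weights are
    the inverse class frequencies of this map, normalised to mean 1.
    """
    lab = labels.labels if isinstance(labels, InstanceLabelMap) else np.asarray(labels)
    fg = lab > 0
    if cfg.class_weights is not None:
        cw = np.asarray(cfg.class_weights, dtype=np.float64)
    else:
        counts = np.array([(~fg).sum(), fg.sum()], dtype=np.float64)
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        cw = inv / inv[counts > 0].mean() if (counts > 0).any() else np.ones(2)
    weights = np.where(fg, cw[1] if cw.size > 1 else cw[0], cw[0]).astype(np.float64)
    if cfg.boundary_weight > 1.0 and fg.any():
        boundary = np.zeros_like(fg)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                shifted = np.full_like(lab, -1)
                h, w = lab.shape
                shifted[max(dr, 0):h + min(dr, 0), max(dc, 0):w + min(dc, 0)] = \
                    lab[max(-dr, 0):h + min(-dr, 0), max(-dc, 0):w + min(-dc, 0)]
                boundary |= fg & (shifted != lab) & (shifted >= 0)
        size = 2 * cfg.boundary_radius + 1
        near = ndimage.binary_dilation(boundary, structure=np.ones((size, size), bool))
        weights[near] *= cfg.boundary_weight
    return weights


def combined_loss(
    probs: np.ndarray,
    target: np.ndarray,
    weight_map: np.ndarray,
    cfg: LossConfig,
    return_grad: bool = False,
):
    """Weighted CE + MSE loss on an HxWxC probability map.

    ``target`` is an HxW integer class map; ``weight_map`` holds positive
    per-pixel weights, normalised internally by their total (so uniformly
    rescaling all weights leaves the loss unchanged).  Returns the scalar
    loss, or ``(loss, dL/dprobs)`` when ``return_grad`` is set.
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target)
    weight_map = np.asarray(weight_map, dtype=np.float64)
    if probs.ndim != 3 or target.shape != probs.shape[:2] or weight_map.shape != target.shape:
        raise ValueError("shape mismatch between probabilities, target and weights")
    if (weight_map <= 0).any() or not np.isfinite(weight_map).all():
        raise ValueError("weight map entries must be positive and finite")
    n_classes = probs.shape[2]
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError("target contains invalid class indices")
    onehot = np.eye(n_classes)[target]
    wsum = weight_map.sum()
    wn = weight_map / wsum
    eps = 1e-12
    p_true = np.take_along_axis(probs, target[..., None], axis=2)[..., 0]
    ce = float(np.sum(wn * -np.log(np.maximum(p_true, eps))))
    sq = ((probs - onehot) ** 2).sum(axis=2)
    mse = float(np.sum(wn * sq))
    loss = cfg.w_ce * ce + cfg.w_mse * mse
    if not return_grad:
        return loss
    dce = np.zeros_like(probs)
    np.put_along_axis(
        dce, target[..., None],
        (-1.0 / np.maximum(p_true, eps) * wn)[..., None], axis=2,
    )
    dmse = 2.0 * (probs - onehot) * wn[..., None]
    return loss, cfg.w_ce * dce + cfg.w_mse * dmse


def _as_batch(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([im.transpose(2, 0, 1) for im in images])


def train(
    model: UNet,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    train_cfg: TrainConfig,
    loss_cfg: LossConfig,
) -> list[float]:
    """Train in place; returns the per-epoch mean loss history.

    ``dataset`` is a list of ``(image HxWx3 float, labels HxW int)`` pairs;
    labels are binarised to background/foreground classes.  Fully
    deterministic under ``train_cfg.seed``.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    shape0 = dataset[0][0].shape
    for im, lab in dataset:
        if im.shape != shape0 or lab.shape != shape0[:2]:
            raise ValueError("inconsistent image/label sizes in the dataset")
    classes = [np.asarray(lab > 0, dtype=np.int64) for _im, lab in dataset]
    weights = [make_weight_map(lab, loss_cfg) for _im, lab in dataset]
    images = [np.asarray(im, dtype=np.float64) for im, _lab in dataset]
    rng = np.random.default_rng(train_cfg.seed)
    opt = SGD(model.params(), lr=train_cfg.learning_rate, l2_lambda=train_cfg.l2_lambda,
              grad_clip=train_cfg.grad_clip)
    history: list[float] = []
    step = 0
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                break
            idx = order[start:start + train_cfg.batch_size]
            xb = _as_batch([images[i] for i in idx])
            logits = model.forward(xb, train=True, rng=rng)
            probs = nnet.softmax(logits, axis=1)
            batch_loss = 0.0
            dlogits = np.empty_like(logits)
            for k, i in enumerate(idx):
                p = probs[k].transpose(1, 2, 0)
                loss_k, dp = combined_loss(p, classes[i], weights[i], loss_cfg, return_grad=True)
                batch_loss += loss_k
                dprobs = dp.transpose(2, 0, 1) / len(idx)
                dlogits[k] = nnet.softmax_backward(probs[k], dprobs, axis=0)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            step += 1
            epoch_losses.append(batch_loss / len(idx))
        history.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
            break
    return history


def predict_probmap(model: UNet, image: HEImage | np.ndarray) -> np.ndarray:
    """Predict an HxWxC per-pixel class-probability map (dropout off)."""
    px = image.pixels if isinstance(image, HEImage) else np.asarray(image, dtype=np.float64)
    logits = model.forward(px.transpose(2, 0, 1)[None], train=False)
    probs = nnet.softmax(logits, axis=1)[0].transpose(1, 2, 0)
    validate_probmap(probs)
    return probs
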