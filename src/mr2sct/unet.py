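"""U-net MR→HU regressor with pure-NumPy layers and backpropagation.

The network follows the classical U-net image-to-image contract adapted for
regression: a contracting path of paired 3×3 convolutions (each followed by
batch normalization and leaky ReLU) with 2×2 max-pooling and channel
doubling per stage, an expansive path of 2×2 up-convolutions that halve the
channels, concatenation with the equal-resolution contracting feature map
and two further conv blocks, dropout at the two deepest stages, and a final
1×1 convolution to a single HU channel.  With ``depth`` resolution levels
the convolutional-layer count (counting up-convolutions and the final 1×1)
is ``5·depth − 2`` — 23 at the full-size depth-5 configuration.

Training minimizes the L2 distance (mean squared error) between predicted
and true CT after mapping HU targets linearly from [−1024, 2000] to [−1, 1].
All layers implement analytic backprop; gradient correctness is verified
against numerical differentiation in the test suite.  Everything is
deterministic given the training seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .grids import ImageGrid

#: linear HU target scaling applied before the L2 loss
HU_RANGE = (-1024.0, 2000.0)
_HU_CENTER = (HU_RANGE[0] + HU_RANGE[1]) / 2.0
_HU_HALFSPAN = (HU_RANGE[1] - HU_RANGE[0]) / 2.0


def scale_hu(hu: np.ndarray) -> np.ndarray:
    return (hu - _HU_CENTER) / _HU_HALFSPAN


def unscale_hu(y: np.ndarray) -> np.ndarray:
    return y * _HU_HALFSPAN + _HU_CENTER


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` counts resolution levels (depth−1 poolings); ``input_size``
    must be divisible by 2**depth so every 2×2 max-pooling sees an even
    layer (the seamless-tiling constraint).
    """

    input_size: int = 64
    depth: int = 3
    base_channels: int = 8
    leaky_slope: float = 0.01
    dropout_rate: float = 0.5
    pad_mode: str = "same"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.pad_mode not in ("same", "unpadded"):
            raise ValueError("pad_mode must be 'same' or 'unpadded'")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} is not divisible by "
                f"2**depth = {2 ** self.depth}: every 2×2 max-pooling must be "
                "applied to a layer with an even x- and y-size")

    @property
    def conv_layer_count(self) -> int:
        """Total convolutional layers: 2·depth down + 3·(depth−1) up + 1."""
        return 5 * self.depth - 2

    @property
    def channel_plan(self) -> list[int]:
        """Feature channels per resolution level (doubling per stage)."""
        return [self.base_channels * 2 ** i for i in range(self.depth)]


@dataclass(frozen=True)
class TrainCfg:
    loss: str = "L2"
    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0
    split: tuple[float, float] = (0.7, 0.3)

    def __post_init__(self) -> None:
        if self.loss != "L2":
            raise ValueError("only the L2 (mean squared error) loss is supported")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


# --------------------------------------------------------------------------
# layers (float32, NCHW)
# --------------------------------------------------------------------------


class Conv2D:
    """k×k convolution, optional same-padding, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, pad: str, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k - 1) // 2 if pad == "same" else 0
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin, k, k)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        ho = xp.shape[2] - self.k + 1
        wo = xp.shape[3] - self.k + 1
        y = np.zeros((x.shape[0], self.cout, ho, wo), dtype=np.float32)
        for di in range(self.k):
            for dj in range(self.k):
                y += np.einsum("oc,bchw->bohw", self.W[:, :, di, dj],
                               xp[:, :, di:di + ho, dj:dj + wo], optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros_like(xp)
        for di in range(self.k):
            for dj in range(self.k):
                self.dW[:, :, di, dj] = np.einsum(
                    "bohw,bchw->oc", dy, xp[:, :, di:di + ho, dj:dj + wo],
                    optimize=True)
                dxp[:, :, di:di + ho, dj:dj + wo] += np.einsum(
                    "oc,bohw->bchw", self.W[:, :, di, dj], dy, optimize=True)
        self.db[:] = dy.sum(axis=(0, 2, 3))
        p = self.pad
        return dxp[:, :, p:xp.shape[2] - p, p:xp.shape[3] - p] if p else dxp


class UpConv2x2:
    """2×2 transposed convolution with stride 2 (channel-halving up-conv)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.W = (rng.standard_normal((cout, cin, 2, 2)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        b, c, h, w = x.shape
        y = np.empty((b, self.W.shape[0], 2 * h, 2 * w), dtype=np.float32)
        for di in range(2):
            for dj in range(2):
                y[:, :, di::2, dj::2] = np.einsum(
                    "oc,bchw->bohw", self.W[:, :, di, dj], x, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.zeros_like(x)
        for di in range(2):
            for dj in range(2):
                sub = dy[:, :, di::2, dj::2]
                self.dW[:, :, di, dj] = np.einsum("bohw,bchw->oc", sub, x,
                                                  optimize=True)
                dx += np.einsum("oc,bohw->bchw", self.W[:, :, di, dj], sub,
                                optimize=True)
        self.db[:] = dy.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2D:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._xhat, self._invstd = xhat, invstd
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[:] = np.einsum("bchw,bchw->c", dy, xhat, optimize=True)
        self.dbeta[:] = dy.sum(axis=(0, 2, 3))
        g = self.gamma * invstd / n
        return (g[None, :, None, None]
                * (n * dy - self.dbeta[None, :, None, None]
                   - xhat * self.dgamma[None, :, None, None])).astype(np.float32)


class LeakyReLU:
    def __init__(self, slope: float):
        self.slope = np.float32(slope)

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._neg = x < 0
        y = x.copy()
        y[self._neg] *= self.slope
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy.copy()
        dx[self._neg] *= self.slope
        return dx


class MaxPool2x2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max-pooling requires an even layer size")
        v = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(b, c, h // 2, w // 2, 4)
        self._arg = v.argmax(axis=-1)
        self._shape = x.shape
        return v.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dv = np.zeros((b, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dv, self._arg[..., None], dy[..., None], axis=-1)
        dv = dv.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dv.reshape(b, c, h, w)


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------


def _center_crop(x: np.ndarray, h: int, w: int) -> np.ndarray:
    dh = (x.shape[2] - h) // 2
    dw = (x.shape[3] - w) // 2
    return x[:, :, dh:dh + h, dw:dw + w]


class UNet:
    """Encoder-decoder with skip connections; see module docstring."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        self.init_weights(seed)

    def init_weights(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        cfg = self.config
        pad = "same" if cfg.pad_mode == "same" else "valid"
        ch = cfg.channel_plan
        self.down_blocks = []
        cin = 1
        for i, c in enumerate(ch):
            block = [Conv2D(cin, c, 3, pad, rng), BatchNorm2D(c),
                     LeakyReLU(cfg.leaky_slope),
                     Conv2D(c, c, 3, pad, rng), BatchNorm2D(c),
                     LeakyReLU(cfg.leaky_slope)]
            # dropout modules at the two deepest contracting stages
            if cfg.depth >= 2 and i >= cfg.depth - 2:
                block.append(Dropout(cfg.dropout_rate))
            self.down_blocks.append(block)
            cin = c
        self.pools = [MaxPool2x2() for _ in range(cfg.depth - 1)]
        self.up_stages = []
        for i in range(cfg.depth - 2, -1, -1):
            c = ch[i]
            stage = {
                "up": UpConv2x2(ch[i + 1], c, rng),
                "convs": [Conv2D(2 * c, c, 3, pad, rng), BatchNorm2D(c),
                          LeakyReLU(cfg.leaky_slope),
                          Conv2D(c, c, 3, pad, rng), BatchNorm2D(c),
                          LeakyReLU(cfg.leaky_slope)],
            }
            self.up_stages.append(stage)
        self.final = Conv2D(ch[0], 1, 1, "valid", rng)
        # per-layer dropout streams re-seeded per training run
        self._dropout_layers = [l for b in self.down_blocks for l in b
                                if isinstance(l, Dropout)]

    # -- introspection -----------------------------------------------------

    def conv_layers(self) -> list:
        """All convolutional layers in execution order (incl. up-convs, 1×1)."""
        out = []
        for b in self.down_blocks:
            out.extend(l for l in b if isinstance(l, Conv2D))
        for s in self.up_stages:
            out.append(s["up"])
            out.extend(l for l in s["convs"] if isinstance(l, Conv2D))
        out.append(self.final)
        return out

    @property
    def conv_layer_count(self) -> int:
        return len(self.conv_layers())

    def all_layers(self) -> list:
        out = []
        for b in self.down_blocks:
            out.extend(b)
        for s in self.up_stages:
            out.append(s["up"])
            out.extend(s["convs"])
        out.append(self.final)
        return out

    def params(self):
        out = []
        for l in self.all_layers():
            out.extend(l.params())
        return out

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cfg = self.config
        skips = []
        h = x.astype(np.float32)
        for i, block in enumerate(self.down_blocks):
            for layer in block:
                h = layer.forward(h, train)
            if i < cfg.depth - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        self._concat_channels = []
        for stage, skip in zip(self.up_stages, reversed(skips)):
            h = stage["up"].forward(h, train)
            skip_c = _center_crop(skip, h.shape[2], h.shape[3])
            assert skip_c.shape[1] == h.shape[1], \
                "skip connection must join equal channel counts"
            self._concat_channels.append(h.shape[1])
            h = np.concatenate([skip_c, h], axis=1)
            for layer in stage["convs"]:
                h = layer.forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dy: np.ndarray) -> None:
        h = self.final.backward(dy.astype(np.float32))
        skip_grads = []
        for stage, cc in zip(reversed(self.up_stages),
                             reversed(self._concat_channels)):
            for layer in reversed(stage["convs"]):
                h = layer.backward(h)
            skip_grads.append(h[:, :h.shape[1] - cc])
            h = stage["up"].backward(h[:, h.shape[1] - cc:])
        # reversed(up_stages) visits shallow levels first, so skip_grads is
        # already indexed by contracting level
        cfg = self.config
        for i in range(cfg.depth - 1, -1, -1):
            if i < cfg.depth - 1:
                h = self.pools[i].backward(h)
                g = skip_grads[i]
                if g.shape != h.shape:  # unpadded mode: un-crop
                    full = np.zeros_like(h)
                    dh = (h.shape[2] - g.shape[2]) // 2
                    dw = (h.shape[3] - g.shape[3]) // 2
                    full[:, :, dh:dh + g.shape[2], dw:dw + g.shape[3]] = g
                    g = full
                h = h + g
            for layer in reversed(self.down_blocks[i]):
                h = layer.backward(h)


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct the network; raises if the seamless-tiling constraint fails."""
    return UNet(config, seed=seed)


# --------------------------------------------------------------------------
# training and prediction
# --------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted MR→HU predictor plus its scaling constants and provenance."""

    config: UNetConfig
    net: UNet
    loss_trace: list[float]
    mr_mean: float
    mr_sd: float
    hu_center: float = _HU_CENTER
    hu_halfspan: float = _HU_HALFSPAN
    standard_scale_fingerprint: str | None = None
    meta: dict = field(default_factory=dict)


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _as_array(img) -> np.ndarray:
    return img.data if isinstance(img, ImageGrid) else np.asarray(img, float)


def train(model: UNet, pairs: list, cfg: TrainCfg,
          standard_scale_fingerprint: str | None = None) -> TrainedModel:
    """Fit the network on (standardized MR, registered CT) pairs.

    Weights are (re-)initialized from ``cfg.seed`` so the run is fully
    reproducible; HU targets are scaled to [−1, 1] and MR inputs to zero
    mean / unit SD over the training set.  Returns the fitted model with its
    per-epoch loss trace.  A non-finite loss aborts with a diagnostic.
    """
    if not pairs:
        raise ValueError("train requires at least one (MR, CT) pair")
    for mr, _ in pairs:
        if isinstance(mr, ImageGrid) and mr.units == "arbitrary":
            raise ValueError("MR inputs must be standardized before training")
    model.init_weights(cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    for i, d in enumerate(model._dropout_layers):
        d.rng = np.random.default_rng(cfg.seed + 100 + i)

    x = np.stack([_as_array(mr) for mr, _ in pairs])[:, None].astype(np.float32)
    y = np.stack([_as_array(ct) for _, ct in pairs])[:, None]
    y = scale_hu(y).astype(np.float32)
    mr_mean = float(x.mean())
    mr_sd = float(x.std()) or 1.0
    x = (x - mr_mean) / mr_sd

    opt = _Adam(model.params(), cfg.learning_rate)
    n = len(pairs)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            pred = model.forward(xb, train=True)
            if pred.shape != yb.shape:  # unpadded mode: compare on the crop
                yb = _center_crop(yb, pred.shape[2], pred.shape[3])
            diff = pred - yb
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            model.backward(2.0 * diff / diff.size)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return TrainedModel(config=model.config, net=model, loss_trace=trace,
                        mr_mean=mr_mean, mr_sd=mr_sd,
                        standard_scale_fingerprint=standard_scale_fingerprint)


def predict(model: TrainedModel, mr) -> ImageGrid:
    """Predict a synthetic CT (HU) from a standardized MR slice."""
    if isinstance(mr, ImageGrid) and mr.units != "standardized":
        raise ValueError(
            "predict requires MR standardized with the training StandardScale "
            f"(units flag is {mr.units!r})")
    arr = _as_array(mr).astype(np.float32)
    x = (arr[None, None] - model.mr_mean) / model.mr_sd
    t0 = time.perf_counter()
    out = model.net.forward(x, train=False)[0, 0]
    runtime = time.perf_counter() - t0
    hu = unscale_hu(out.astype(np.float64))
    spacing = mr.spacing if isinstance(mr, ImageGrid) else (1.0, 1.0)
    return ImageGrid(hu, spacing=spacing, modality="CT", units="HU",
                     meta={"synthetic": True, "predict_seconds": runtime})
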