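"""A compact CPU U-Net written on numpy.

Standard encoder-decoder with skip connections: each encoder stage is two
3x3 same-padding convolutions + ReLU followed by 2x2 max pooling, filter
count doubling per stage; the decoder mirrors it with nearest-neighbour
2x upsampling and channel concatenation of the skip tensor; a final 1x1
convolution maps to per-class scores, normalized per pixel by softmax.

Convolutions run as im2col + BLAS matmul in float32 with hand-written
backward passes; this is fast enough for desk-scale training (64x64 frames,
depth 2) on a single CPU core and keeps the whole pipeline free of any
deep-learning runtime.  All shapes are NCHW.
"""

from __future__ import annotations

import numpy as np


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d:
    """k x k same-padding convolution with bias (k odd)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.W = _he_init(rng, (c_out, c_in * k * k), c_in * k * k)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        s = x.strides
        view = np.lib.stride_tricks.as_strided(
            x, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3])
        )
        return np.ascontiguousarray(view).reshape(n, c * k * k, h * w)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, _, h, w = x.shape
        cols = self._im2col(x.astype(np.float32, copy=False))
        out = np.matmul(self.W[None], cols) + self.b[None, :, None]
        if train:
            self._cols, self._x_shape = cols, x.shape
        else:
            self._cols = None
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._x_shape is not None
        n, c, h, w = self._x_shape
        k, p = self.k, self.k // 2
        dm = dout.reshape(n, self.c_out, h * w).astype(np.float32, copy=False)
        self.dW = np.einsum("nfp,ncp->fc", dm, self._cols, optimize=True)
        self.db = dm.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], dm)  # (n, c*k*k, h*w)
        dcols = dcols.reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, ki, kj]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    @property
    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class LeakyReLU:
    """Leaky rectifier (slope ``alpha`` for negative inputs).

    The small negative slope keeps units trainable at the aggressive
    learning rates short CPU runs need (a hard ReLU can die irreversibly
    there).
    """

    def __init__(self, alpha: float = 0.1) -> None:
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.where(x > 0, x, self.alpha * x)
        if train:
            self._mask = x > 0
        return out.astype(np.float32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dout * np.where(self._mask, 1.0, self.alpha).astype(np.float32)


class InstanceNorm:
    """Per-sample, per-channel normalization with learnable affine.

    Normalizes each (sample, channel) plane to zero mean / unit variance
    over its spatial extent, then applies a channel-wise scale and shift.
    Stabilizes small-batch SGD training enough that short schedules
    converge reliably; statistics are per-sample, so inference needs no
    running averages and stays deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._istd: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        if train:
            self._xhat, self._istd = xhat, istd
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._xhat is not None and self._istd is not None
        xhat, istd = self._xhat, self._istd
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        dx = istd * (dxhat - m1 - xhat * m2)
        self._xhat = self._istd = None
        return dx.astype(np.float32, copy=False)


class MaxPool2:
    """2x2 max pooling, stride 2; ties resolved to the first occurrence."""

    def __init__(self) -> None:
        self._onehot: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(n, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._onehot = np.eye(4, dtype=np.float32)[idx]
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._onehot is not None and self._shape is not None
        n, c, h, w = self._shape
        dv = self._onehot * dout[..., None]
        dv = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dv.reshape(n, c, h, w)


class UpsampleNearest2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _ConvBlock:
    """Two (conv 3x3 -> instance norm -> leaky ReLU) stages."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.norm1 = InstanceNorm(c_out)
        self.relu1 = LeakyReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.norm2 = InstanceNorm(c_out)
        self.relu2 = LeakyReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.norm1.forward(self.conv1.forward(x, train), train), train)
        return self.relu2.forward(self.norm2.forward(self.conv2.forward(h, train), train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.conv2.backward(self.norm2.backward(self.relu2.backward(dout)))
        return self.conv1.backward(self.norm1.backward(self.relu1.backward(d)))

    @property
    def convs(self) -> list[Conv2d]:
        return [self.conv1, self.conv2]

    @property
    def norms(self) -> list[InstanceNorm]:
        return [self.norm1, self.norm2]


class UNet:
    """U-Net of configurable depth and width for square inputs.

    ``in_size`` must be divisible by 2**depth so every pooled grid is
    integral.
    """

    def __init__(
        self,
        in_size: int,
        n_classes: int = 5,
        depth: int = 4,
        base_filters: int = 32,
        in_channels: int = 1,
        seed: int = 0,
        input_norm: str = "standard",
        coord_channels: bool = True,
    ):
        if in_size % (2**depth) != 0:
            raise ValueError(f"in_size {in_size} not divisible by 2^{depth}")
        if input_norm not in ("unit", "standard"):
            raise ValueError(f"unknown input_norm {input_norm!r}")
        self.in_size = in_size
        self.n_classes = n_classes
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.seed = seed
        self.input_norm = input_norm
        self.coord_channels = coord_channels
        rng = np.random.default_rng(seed)

        widths = [base_filters * 2**i for i in range(depth)]
        self.enc = []
        c = in_channels + (2 if coord_channels else 0)
        for wdt in widths:
            self.enc.append(_ConvBlock(c, wdt, rng))
            c = wdt
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _ConvBlock(c, base_filters * 2**depth, rng)
        c = base_filters * 2**depth
        self.ups = []
        self.dec = []
        for wdt in reversed(widths):
            self.ups.append(UpsampleNearest2())
            self.dec.append(_ConvBlock(c + wdt, wdt, rng))
            c = wdt
        self.final = Conv2d(c, n_classes, 1, rng)
        self._skip_channels = list(reversed(widths))

    # -- forward / backward -------------------------------------------------

    def _append_coords(self, x: np.ndarray) -> np.ndarray:
        """Concatenate normalized (row, col) coordinate channels in [-1, 1].

        Coordinates describe the output grid, so they are never flipped or
        rotated with the image: they hand the network its absolute position
        (a plain conv stack can only infer it weakly from border padding),
        which anchors left/right chamber identity.
        """
        n, _, h, w = x.shape
        rows = np.linspace(-1.0, 1.0, h, dtype=np.float32)[:, None]
        cols = np.linspace(-1.0, 1.0, w, dtype=np.float32)[None, :]
        rc = np.broadcast_to(rows, (h, w))
        cc = np.broadcast_to(cols, (h, w))
        coords = np.broadcast_to(np.stack([rc, cc]), (n, 2, h, w))
        return np.concatenate([x, coords], axis=1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits of shape (N, n_classes, H, W) for input (N, C, H, W)."""
        skips = []
        h = x.astype(np.float32, copy=False)
        if self.coord_channels:
            h = self._append_coords(h)
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            u = up.forward(h, train)
            h = blk.forward(np.concatenate([skip, u], axis=1), train)
        return self.final.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        dskips: list[np.ndarray] = []
        for up, blk, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            dcat = blk.backward(d)
            dskips.append(dcat[:, :c_skip])
            d = up.backward(dcat[:, c_skip:])
        d = self.bottleneck.backward(d)
        # dskips was filled decoder-last-first = encoder-stage order 0..depth-1
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d) + dskip
            d = blk.backward(d)

    # -- parameters ---------------------------------------------------------

    def conv_layers(self) -> list[Conv2d]:
        layers: list[Conv2d] = []
        for blk in self.enc:
            layers += blk.convs
        layers += self.bottleneck.convs
        for blk in self.dec:
            layers += blk.convs
        layers.append(self.final)
        return layers

    def norm_layers(self) -> list[InstanceNorm]:
        layers: list[InstanceNorm] = []
        for blk in self.enc:
            layers += blk.norms
        layers += self.bottleneck.norms
        for blk in self.dec:
            layers += blk.norms
        return layers

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.conv_layers()):
            out[f"conv{i}_W"] = layer.W.copy()
            out[f"conv{i}_b"] = layer.b.copy()
        for i, norm in enumerate(self.norm_layers()):
            out[f"norm{i}_gamma"] = norm.gamma.copy()
            out[f"norm{i}_beta"] = norm.beta.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.conv_layers()):
            layer.W[...] = weights[f"conv{i}_W"]
            layer.b[...] = weights[f"conv{i}_b"]
        for i, norm in enumerate(self.norm_layers()):
            norm.gamma[...] = weights[f"norm{i}_gamma"]
            norm.beta[...] = weights[f"norm{i}_beta"]


class SGDMomentum:
    """Classic SGD with momentum and (L2) weight decay on the kernels.

    v <- mu*v - lr*(g + wd*w);  w <- w + v.  Biases are excluded from
    weight decay.
    """

    def __init__(self, model: UNet, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [
            (np.zeros_like(layer.W), np.zeros_like(layer.b))
            for layer in model.conv_layers()
        ]
        self._vel_norm = [
            (np.zeros_like(norm.gamma), np.zeros_like(norm.beta))
            for norm in model.norm_layers()
        ]

    def step(self) -> None:
        for layer, (vW, vb) in zip(self.model.conv_layers(), self._vel):
            gW = layer.dW + self.weight_decay * layer.W
            vW *= self.momentum
            vW -= self.lr * gW
            layer.W += vW
            vb *= self.momentum
            vb -= self.lr * layer.db
            layer.b += vb
        # norm affine parameters: momentum but no weight decay
        for norm, (vg, vbeta) in zip(self.model.norm_layers(), self._vel_norm):
            vg *= self.momentum
            vg -= self.lr * norm.dgamma
            norm.gamma += vg
            vbeta *= self.momentum
            vbeta -= self.lr * norm.dbeta
            norm.beta += vbeta


def clip_gradients(model: UNet, max_norm: float) -> float:
    """Scale all parameter gradients so their global L2 norm <= max_norm.

    Returns the pre-clip norm.  Standard stabilizer for SGD at aggressive
    learning rates; a no-op once training settles.
    """
    total = 0.0
    layers = model.conv_layers()
    norms = model.norm_layers()
    for layer in layers:
        total += float((layer.dW**2).sum()) + float((layer.db**2).sum())
    for n in norms:
        total += float((n.dgamma**2).sum()) + float((n.dbeta**2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for layer in layers:
            layer.dW *= scale
            layer.db *= scale
        for n in norms:
            n.dgamma *= scale
            n.dbeta *= scale
    return norm


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_with_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    ``labels`` is integer (N, H, W) with values in [0, n_classes).
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    flat = p.transpose(0, 2, 3, 1).reshape(-1, k)
    lab = labels.reshape(-1)
    picked = np.clip(flat[np.arange(flat.size // k), lab], 1e-12, None)
    loss = float(-np.log(picked).mean())
    dflat = flat.copy()
    dflat[np.arange(flat.size // k), lab] -= 1.0
    dflat /= flat.shape[0]
    dlogits = dflat.reshape(n, h, w, k).transpose(0, 3, 1, 2)
    return loss, dlogits.astype(np.float32)
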