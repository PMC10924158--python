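"""A 2-D U-net in plain NumPy with hand-written backpropagation.

Architecture for depth D (the number of paired convolutional blocks in
the encoder and, symmetrically, in the decoder):

* encoder: D paired blocks (two 3x3 convolutions + ReLU each), a 2x2
  max-pool after every block;
* bottleneck: one paired block at the deepest resolution with dropout;
* decoder: D stages of nearest-neighbor 2x upsampling, a 3x3 convolution
  halving the channels, concatenation with the encoder skip, and a
  paired block;
* head: 1x1 convolution to one channel, sigmoid.

Filters double per level from ``base_filters``. Inputs are single-channel
(C, H, W) arrays with H and W divisible by 2**D. Everything is seeded:
weight init (He) and dropout draw from generators owned by the model.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, H, W) -> (C*k*k, H*W) patch matrix with same-padding."""
    c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    cols = np.empty((c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xp[:, i : i + h, j : j + w]
    return cols.reshape(c * k * k, h * w)


def _col2im(cols: np.ndarray, c: int, h: int, w: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (C, H, W)."""
    p = k // 2
    out = np.zeros((c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            out[:, i : i + h, j : j + w] += cols[:, i, j]
    return out[:, p : p + h, p : p + w] if p else out


class Conv2D:
    """k x k same-padding convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k * k))  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, (out_ch, in_ch * k * k))
        self.b = np.zeros(out_ch)
        self.k = k
        self.in_ch = in_ch
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        _, h, w = x.shape
        cols = _im2col(x, self.k)
        self._cols, self._shape = cols, (h, w)
        return (self.W @ cols + self.b[:, None]).reshape(-1, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._shape
        dy2 = dy.reshape(dy.shape[0], -1)
        self.dW = dy2 @ self._cols.T
        self.db = dy2.sum(axis=1)
        dcols = self.W.T @ dy2
        return _col2im(dcols, self.in_ch, h, w, self.k)

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        r = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, h // 2, w // 2, 4
        )
        self._arg = r.argmax(axis=3)
        self._in_shape = (c, h, w)
        return r.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        flat = np.zeros((c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=3)
        return (
            flat.reshape(c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 3, 2, 4)
            .reshape(c, h, w)
        )


class UpNearest2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = dy.shape
        return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train and self.p > 0:
            self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        else:
            self._mask = 1.0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _PairedBlock:
    """Two 3x3 conv + ReLU stages; the unit in which network depth is counted."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.c1 = Conv2D(in_ch, out_ch, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2D(out_ch, out_ch, 3, rng)
        self.r2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))

    @property
    def convs(self):
        return [self.c1, self.c2]


class UNet2D:
    def __init__(
        self,
        depth: int,
        base_filters: int = 16,
        in_ch: int = 1,
        dropout_p: float = 0.0,
        seed: int = 0,
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
        self.depth = depth
        self.base_filters = base_filters
        self.in_ch = in_ch
        self._drop_rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, 12])
        )
        ch = [base_filters * 2**i for i in range(depth + 1)]
        self.enc = [
            _PairedBlock(in_ch if i == 0 else ch[i - 1], ch[i], rng)
            for i in range(depth)
        ]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _PairedBlock(ch[depth - 1], ch[depth], rng)
        self.dropout = Dropout(dropout_p, self._drop_rng)
        self.ups = [UpNearest2() for _ in range(depth)]
        self.up_convs = [
            Conv2D(ch[i + 1], ch[i], 3, rng) for i in reversed(range(depth))
        ]
        self.dec = [
            _PairedBlock(2 * ch[i], ch[i], rng) for i in reversed(range(depth))
        ]
        self.out_conv = Conv2D(ch[0], 1, 1, rng)

    # -- introspection -------------------------------------------------

    def conv_layers(self) -> list[Conv2D]:
        layers: list[Conv2D] = []
        for blk in self.enc:
            layers += blk.convs
        layers += self.bottleneck.convs
        for up, blk in zip(self.up_convs, self.dec):
            layers.append(up)
            layers += blk.convs
        layers.append(self.out_conv)
        return layers

    def n_paired_blocks(self) -> int:
        """Encoder + decoder paired blocks (the bottleneck is the bridge)."""
        return len(self.enc) + len(self.dec)

    def n_parameters(self) -> int:
        return sum(layer.W.size + layer.b.size for layer in self.conv_layers())

    # -- forward / backward --------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(C, H, W) input -> (H, W) foreground-probability map."""
        if x.ndim == 2:
            x = x[None]
        if x.shape[0] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channel(s), got {x.shape[0]}")
        div = 2**self.depth
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be divisible by 2**depth = {div}"
            )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        x = self.dropout.forward(x, train)
        for up, upc, blk, skip in zip(self.ups, self.up_convs, self.dec, reversed(skips)):
            x = upc.forward(up.forward(x))
            x = np.concatenate([skip, x], axis=0)
            x = blk.forward(x)
        z = self.out_conv.forward(x)[0]
        self._prob = 1.0 / (1.0 + np.exp(-z))
        return self._prob

    def backward(self, dz: np.ndarray) -> None:
        """Back-propagate a gradient w.r.t. the pre-sigmoid logits."""
        d = self.out_conv.backward(dz[None])
        skip_grads = []
        for up, upc, blk in zip(
            reversed(self.ups), reversed(self.up_convs), reversed(self.dec)
        ):
            d = blk.backward(d)
            n_skip = d.shape[0] // 2
            skip_grads.append(d[:n_skip])
            d = up.backward(upc.backward(d[n_skip:]))
        d = self.dropout.backward(d)
        d = self.bottleneck.backward(d)
        # skip_grads[j] pairs with skips[j] (encoder block j); the encoder
        # is walked deepest-first here, so reverse them to match
        for blk, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            d = pool.backward(d) + gskip
            d = blk.backward(d)

    def grads(self):
        for layer in self.conv_layers():
            yield layer.dW, layer.db

    def weights(self):
        for layer in self.conv_layers():
            yield layer.W, layer.b

    # -- serialization --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.conv_layers()):
            out[f"W{i}"] = layer.W
            out[f"b{i}"] = layer.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.conv_layers()):
            layer.W[...] = state[f"W{i}"]
            layer.b[...] = state[f"b{i}"]


class Adam:
    """Adam optimizer over a model's (W, b) parameter pairs."""

    def __init__(self, model: UNet2D, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for pair in model.weights() for p in pair]
        self.v = [np.zeros_like(p) for pair in model.weights() for p in pair]

    def step(self) -> None:
        self.t += 1
        params = [p for pair in self.model.weights() for p in pair]
        grads = [g for pair in self.model.grads() for g in pair]
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
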