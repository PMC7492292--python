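"""Minimal NumPy convolutional network engine for the vertebra U-Net.

Implements exactly the pieces the segmentation model needs — 3x3 "same"
convolutions, ReLU, 2x2 max-pooling, nearest-neighbour upsampling, skip
concatenation, a sigmoid head, the soft-Jaccard loss gradient, and Adam —
with hand-derived backward passes.  Convolutions are lowered to matrix
multiplies via im2col (``sliding_window_view``) so single-CPU training of
reduced-scale models is practical.  All arithmetic is float32; all
randomness flows through an explicit ``numpy.random.Generator``, so training
and inference are bit-reproducible for a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """[N,H,W,C] -> [N*H*W, k*k*C] patches with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    # windows over spatial dims: [N, H, W, C, k, k] -> [..., k, k, C]
    cols = sliding_window_view(xp, (k, k), axis=(1, 2))
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
    n, h, w = x.shape[:3]
    return cols.reshape(n * h * w, k * k * x.shape[3])


class Conv2D:
    """3x3 (or kxk) stride-1 'same' convolution with bias."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * c_in
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W.reshape(-1, self.W.shape[-1]) + self.b
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c_out = dy.shape
        dy2 = dy.reshape(-1, c_out)
        self.dW[...] = (self._cols.T @ dy2).reshape(self.W.shape)
        self.db[...] = dy2.sum(axis=0)
        self._cols = None
        # dx: full correlation of dy with the 180deg-rotated, channel-swapped kernel
        w_rot = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # [k,k,c_out,c_in]
        cols_dy = _im2col(dy, self.k)
        dx = cols_dy @ w_rot.reshape(-1, w_rot.shape[-1])
        return dx.reshape(self._x_shape)


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            # route gradient to the (first) argmax of each 2x2 window
            self._mask = xr == out[:, :, None, :, None, :]
            self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dy.shape
        dyr = dy[:, :, None, :, None, :] * self._mask
        # normalise ties so gradient mass is conserved
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        dyr = dyr / counts
        return dyr.reshape(self._shape)


class Upsample2x:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class UNet:
    """Depth-``depth`` U-Net with ``base`` filters at the top level.

    Contracting path: (conv-ReLU)x2 then 2x2 max-pool per level; expansive
    path: 2x upsample, 3x3 conv halving channels, skip concatenation and
    (conv-ReLU)x2; single-channel 1x1 sigmoid head.
    """

    def __init__(self, in_channels: int = 4, base: int = 64, depth: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc: list[list] = []
        c_prev = in_channels
        for d in range(depth):
            f = base * 2**d
            self.enc.append([Conv2D(c_prev, f, rng=rng), ReLU(), Conv2D(f, f, rng=rng), ReLU()])
            c_prev = f
        f = base * 2**depth
        self.bottleneck = [Conv2D(c_prev, f, rng=rng), ReLU(), Conv2D(f, f, rng=rng), ReLU()]
        c_prev = f
        self.dec: list[dict] = []
        for d in reversed(range(depth)):
            f = base * 2**d
            self.dec.append(
                {
                    "up": Upsample2x(),
                    "upconv": Conv2D(c_prev, f, rng=rng),
                    "uprelu": ReLU(),
                    "convs": [Conv2D(2 * f, f, rng=rng), ReLU(), Conv2D(f, f, rng=rng), ReLU()],
                }
            )
            c_prev = f
        self.head = Conv2D(c_prev, 1, k=1, rng=rng)
        self.pools = [MaxPool2x2() for _ in range(depth)]

    def fold_input_scaling(self, mean: np.ndarray, std: np.ndarray) -> None:
        """Fold per-channel standardisation into the first conv layer.

        Rescales the first layer's kernel by ``1/std`` per input channel and
        shifts its bias so the layer computes what it would on
        ``(x - mean)/std`` — a scale-aware initialisation that keeps the
        input data itself untouched while preventing sigmoid saturation when
        channel magnitudes differ by orders of magnitude.  Called once,
        before any training step; the adjustment lives in the weights, so
        saved checkpoints need no side information.
        """
        conv = self.enc[0][0]
        std = np.asarray(std, dtype=np.float32)
        mean = np.asarray(mean, dtype=np.float32)
        std = np.where(std > 0, std, 1.0)
        conv.W /= std[None, None, :, None]
        conv.b -= (conv.W * mean[None, None, :, None]).sum(axis=(0, 1, 2))

    # -- parameter plumbing -------------------------------------------------

    def layers(self):
        for block in self.enc:
            yield from block
        yield from self.bottleneck
        for d in self.dec:
            yield d["upconv"]
            yield from d["convs"]
        yield self.head

    def parameters(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self.layers():
            out.extend(layer.grads)
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """[N,H,W,C] float32 -> logits [N,H,W]."""
        skips = []
        h = x.astype(np.float32, copy=False)
        for d, block in enumerate(self.enc):
            for layer in block:
                h = layer.forward(h, train)
            skips.append(h)
            h = self.pools[d].forward(h, train)
        for layer in self.bottleneck:
            h = layer.forward(h, train)
        self._skip_channels = []
        for d, dec in enumerate(self.dec):
            h = dec["up"].forward(h, train)
            h = dec["uprelu"].forward(dec["upconv"].forward(h, train), train)
            skip = skips[self.depth - 1 - d]
            h = np.concatenate([skip, h], axis=-1)
            self._skip_channels.append(skip.shape[-1])
            for layer in dec["convs"]:
                h = layer.forward(h, train)
        z = self.head.forward(h, train)
        return z[..., 0]

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits) [N,H,W] through the network."""
        g = self.head.backward(dz[..., None].astype(np.float32))
        # dec[d] consumed the skip from encoder level depth-1-d
        dskip_by_level: dict[int, np.ndarray] = {}
        for d in reversed(range(len(self.dec))):
            dec = self.dec[d]
            for layer in reversed(dec["convs"]):
                g = layer.backward(g)
            c_skip = self._skip_channels[d]
            dskip_by_level[self.depth - 1 - d] = g[..., :c_skip]
            g = g[..., c_skip:]
            g = dec["upconv"].backward(dec["uprelu"].backward(g))
            g = dec["up"].backward(g)
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        for d in reversed(range(self.depth)):
            # the skip tensor fed both the pool and the decoder concat
            g = self.pools[d].backward(g) + dskip_by_level[d]
            for layer in reversed(self.enc[d]):
                g = layer.backward(g)


class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_jaccard_loss_and_grad(
    y_true: np.ndarray,
    z: np.ndarray,
    smooth: float = 100.0,
    bce_weight: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Mean per-slice soft-Jaccard distance and its gradient w.r.t. logits.

    Per slice: ``L = 1 - (I + s) / (U + s)`` with ``I = sum(t*p)`` and
    ``U = sum(t) + sum(p) - I`` over pixels, ``p = sigmoid(z)``.

    ``bce_weight`` adds that multiple of the per-pixel binary cross-entropy.
    The Jaccard gradient is proportional to ``p(1-p)`` and vanishes once the
    sigmoid saturates, which makes the all-background solution an absorbing
    basin on class-imbalanced slices; the cross-entropy term's ``p - t``
    gradient never vanishes and keeps rare positives recoverable.
    """
    t = y_true.astype(np.float32)
    zf = z.astype(np.float32)
    p = sigmoid(zf)
    axes = tuple(range(1, t.ndim))
    inter = (t * p).sum(axis=axes)
    union = t.sum(axis=axes) + p.sum(axis=axes) - inter
    loss = float((1.0 - (inter + smooth) / (union + smooth)).mean())
    # dL/dp_i = -[ t_i (U+s) - (I+s)(1-t_i) ] / (U+s)^2
    bshape = (-1,) + (1,) * (t.ndim - 1)
    denom = (union + smooth).reshape(bshape)
    num = t * denom - (inter + smooth).reshape(bshape) * (1.0 - t)
    dz = (-num / denom**2) * p * (1.0 - p)
    if bce_weight > 0.0:
        n_pix = t[0].size
        # stable BCE on logits: max(z,0) - z*t + log(1+exp(-|z|))
        bce = np.maximum(zf, 0.0) - zf * t + np.log1p(np.exp(-np.abs(zf)))
        loss += bce_weight * float(bce.mean())
        dz = dz + bce_weight * (p - t) / n_pix
    dz /= t.shape[0]
    return loss, dz.astype(np.float32)
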