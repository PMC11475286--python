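"""Minimal NumPy neural-network engine for the segmentation model.

Implements exactly the layer set the encoder/ASPP/decoder architecture
needs — strided/dilated 2-D convolution, batch normalization, ReLU, max
pooling, bilinear upsampling, residual addition and a global-pool
context branch — each with a hand-written backward pass. Tensors are
``float32`` in NCHW layout. Convolutions run as a single GEMM over an
im2col patch matrix; the patch gather/scatter loops over the k*k kernel
offsets only, so every inner operation is vectorized.

The engine is intentionally small: no autograd graph, no GPU, no
training tricks beyond what the model requires. Composite blocks wire
their children's ``forward``/``backward`` explicitly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Sequential", "Identity", "Conv2d", "BatchNorm2d",
    "ReLU", "MaxPool2d", "BilinearUpsample", "Residual", "ImagePoolBranch",
    "ASPP", "softmax", "weighted_ce_loss_and_grad",
]

_DT = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=_DT)
        self.grad = np.zeros_like(self.data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Identity(Layer):
    def forward(self, x, train=False):
        return x

    def backward(self, dout):
        return dout


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Conv2d(Layer):
    """2-D convolution with 'same'-style padding for odd kernels.

    Output spatial size is ``ceil(in / stride)``; padding is
    ``dilation * (k - 1) // 2`` per side.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 dilation: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if k % 2 == 0:
            raise ValueError("only odd kernel sizes are supported")
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None
        self.k, self.stride, self.dilation = k, stride, dilation
        self.pad = dilation * (k - 1) // 2
        self.cin, self.cout = cin, cout
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _out_size(self, n: int) -> int:
        eff = self.dilation * (self.k - 1) + 1
        return (n + 2 * self.pad - eff) // self.stride + 1

    def forward(self, x, train=False):
        n, cin, h, w = x.shape
        k, s, d, p = self.k, self.stride, self.dilation, self.pad
        ho, wo = self._out_size(h), self._out_size(w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        patches = np.empty((n, cin, k * k, ho, wo), dtype=_DT)
        for ki in range(k):
            for kj in range(k):
                patches[:, :, ki * k + kj] = xp[
                    :, :, ki * d: ki * d + s * (ho - 1) + 1: s,
                    kj * d: kj * d + s * (wo - 1) + 1: s]
        p2 = patches.reshape(n, cin * k * k, ho * wo)
        w2 = self.w.data.reshape(self.cout, cin * k * k)
        out = np.matmul(w2[None], p2).reshape(n, self.cout, ho, wo)
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        self._cache = (p2, x.shape, (ho, wo))
        return out

    def backward(self, dout):
        p2, xshape, (ho, wo) = self._cache
        n, cin, h, w = xshape
        k, s, d, p = self.k, self.stride, self.dilation, self.pad
        d2 = dout.reshape(n, self.cout, ho * wo)
        w2 = self.w.data.reshape(self.cout, cin * k * k)
        # weight grad: sum_n dout @ patches^T
        dw2 = np.einsum("nfp,ncp->fc", d2, p2, optimize=True)
        self.w.grad += dw2.reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        dp2 = np.matmul(w2.T[None], d2)  # (n, cin*k*k, ho*wo)
        dpatches = dp2.reshape(n, cin, k * k, ho, wo)
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=_DT)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki * d: ki * d + s * (ho - 1) + 1: s,
                    kj * d: kj * d + s * (wo - 1) + 1: s] += dpatches[:, :, ki * k + kj]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=_DT)
        self.running_var = np.ones(c, dtype=_DT)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_DT)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DT)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        xhat = xhat.astype(_DT)
        self._cache = (xhat, ivar.astype(_DT), train)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat, ivar, train = self._cache
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data[None, :, None, None] * ivar[None, :, None, None]
        if not train:
            return g * dout
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        return g * (dout - (dbeta[None, :, None, None]
                            + xhat * dgamma[None, :, None, None]) / m)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool2d(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        out = np.full((n, c, ho, wo), -np.inf, dtype=_DT)
        idx = np.zeros((n, c, ho, wo), dtype=np.int8)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki: ki + s * (ho - 1) + 1: s, kj: kj + s * (wo - 1) + 1: s]
                upd = xs > out
                out[upd] = xs[upd]
                idx[upd] = ki * k + kj
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, (n, c, h, w) = self._cache
        k, s, p = self.k, self.stride, self.pad
        ho, wo = dout.shape[2], dout.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_DT)
        for ki in range(k):
            for kj in range(k):
                view = dxp[:, :, ki: ki + s * (ho - 1) + 1: s,
                           kj: kj + s * (wo - 1) + 1: s]
                sel = idx == ki * k + kj
                view[sel] += dout[sel]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


def _interp_matrix(nout: int, nin: int) -> np.ndarray:
    """Bilinear interpolation matrix (half-pixel-center convention)."""
    a = np.zeros((nout, nin), dtype=_DT)
    if nin == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(nout) + 0.5) * nin / nout - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    i0c = np.clip(i0, 0, nin - 1)
    i1c = np.clip(i0 + 1, 0, nin - 1)
    for r in range(nout):
        a[r, i0c[r]] += 1.0 - frac[r]
        a[r, i1c[r]] += frac[r]
    return a


class BilinearUpsample(Layer):
    """Resample to a fixed target spatial size with bilinear weights."""

    def __init__(self, target: tuple[int, int]):
        self.target = target
        self._ah = None
        self._aw = None

    def forward(self, x, train=False):
        ht, wt = self.target
        if self._ah is None or self._ah.shape != (ht, x.shape[2]):
            self._ah = _interp_matrix(ht, x.shape[2])
            self._aw = _interp_matrix(wt, x.shape[3])
        self._in_shape = x.shape
        tmp = np.tensordot(self._ah, x, axes=(1, 2))  # (Ht, N, C, W)
        out = np.tensordot(tmp, self._aw, axes=(3, 1))  # (Ht, N, C, Wt)
        return np.ascontiguousarray(out.transpose(1, 2, 0, 3), dtype=_DT)

    def backward(self, dout):
        tmp = np.tensordot(self._ah.T, dout.transpose(2, 0, 1, 3), axes=(1, 0))
        dx = np.tensordot(tmp, self._aw, axes=(3, 0))  # (h, N, C, w)
        return np.ascontiguousarray(dx.transpose(1, 2, 0, 3), dtype=_DT)


class Residual(Layer):
    """y = main(x) + shortcut(x); follow with an external ReLU."""

    def __init__(self, main: Layer, shortcut: Layer | None = None):
        self.main = main
        self.shortcut = shortcut or Identity()

    def params(self):
        return self.main.params() + self.shortcut.params()

    def forward(self, x, train=False):
        return self.main.forward(x, train) + self.shortcut.forward(x, train)

    def backward(self, dout):
        return self.main.backward(dout) + self.shortcut.backward(dout)


class ImagePoolBranch(Layer):
    """Global-average-pool context branch: pool -> 1x1 conv/BN/ReLU -> tile."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str = "imgpool"):
        self.inner = Sequential(
            Conv2d(cin, cout, 1, rng=rng, name=f"{name}.conv"),
            BatchNorm2d(cout, name=f"{name}.bn"),
            ReLU(),
        )

    def params(self):
        return self.inner.params()

    def forward(self, x, train=False):
        self._hw = x.shape[2:]
        pooled = x.mean(axis=(2, 3), keepdims=True).astype(_DT)
        z = self.inner.forward(pooled, train)
        return np.broadcast_to(z, (*z.shape[:2], *self._hw)).astype(_DT)

    def backward(self, dout):
        h, w = self._hw
        dz = dout.sum(axis=(2, 3), keepdims=True)
        dpooled = self.inner.backward(dz)
        return (np.broadcast_to(dpooled, (*dpooled.shape[:2], h, w)) / (h * w)).astype(_DT)


class ASPP(Layer):
    """Atrous spatial pyramid pooling: parallel dilated branches + pooling.

    Branches: one 1x1 conv, one 3x3 dilated conv per rate, and a global
    image-pool branch; concatenated along channels and projected back
    with a 1x1 conv.
    """

    def __init__(self, cin: int, branch_ch: int, rates: tuple[int, ...],
                 out_ch: int, rng: np.random.Generator, name: str = "aspp"):
        self.branches: list[Layer] = [Sequential(
            Conv2d(cin, branch_ch, 1, rng=rng, name=f"{name}.b0.conv"),
            BatchNorm2d(branch_ch, name=f"{name}.b0.bn"), ReLU())]
        for i, r in enumerate(rates, start=1):
            self.branches.append(Sequential(
                Conv2d(cin, branch_ch, 3, dilation=r, rng=rng, name=f"{name}.b{i}.conv"),
                BatchNorm2d(branch_ch, name=f"{name}.b{i}.bn"), ReLU()))
        self.branches.append(ImagePoolBranch(cin, branch_ch, rng, name=f"{name}.pool"))
        self.branch_ch = branch_ch
        self.project = Sequential(
            Conv2d(branch_ch * len(self.branches), out_ch, 1, rng=rng,
                   name=f"{name}.proj.conv"),
            BatchNorm2d(out_ch, name=f"{name}.proj.bn"), ReLU())

    def params(self):
        return [p for b in self.branches for p in b.params()] + self.project.params()

    def forward(self, x, train=False):
        outs = [b.forward(x, train) for b in self.branches]
        cat = np.concatenate(outs, axis=1)
        return self.project.forward(cat, train)

    def backward(self, dout):
        dcat = self.project.backward(dout)
        c = self.branch_ch
        dx = None
        for i, b in enumerate(self.branches):
            d = b.backward(dcat[:, i * c:(i + 1) * c])
            dx = d if dx is None else dx + d
        return dx


# ---------------------------------------------------------------------------
# Loss head
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    zs = z - z.max(axis=axis, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_ce_loss_and_grad(
    logits: np.ndarray, truth: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-pixel class-weighted softmax cross-entropy, averaged over pixels.

    Returns the scalar loss and its gradient with respect to the logits
    (shape ``(N, K, H, W)``; ``truth`` is ``(N, H, W)`` integer labels).
    """
    n, k, h, w = logits.shape
    probs = softmax(logits.astype(np.float64), axis=1)
    y = truth.astype(np.int64)
    onehot = np.eye(k)[y].transpose(0, 3, 1, 2)  # (N, K, H, W)
    wmap = np.asarray(class_weights, dtype=np.float64)[y]  # (N, H, W)
    p_true = np.clip((probs * onehot).sum(axis=1), 1e-12, None)
    loss = float(np.mean(wmap * -np.log(p_true)))
    dlogits = (wmap[:, None] * (probs - onehot) / (n * h * w)).astype(_DT)
    return loss, dlogits
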