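"""Minimal NumPy convolutional-network core for the ROI segmenter.

Implements exactly the pieces the nested U-Net needs — 3×3 same-padded
convolution, batch normalization, ReLU, 2×2 max pooling, 2× nearest
upsampling, channel concatenation, a 1×1 sigmoid head — with hand-written
backpropagation and an RMSprop optimizer. Everything runs in float32 on
plain ``numpy``; convolutions are expressed as ``tensordot`` over
``sliding_window_view`` patches, and the backward pass of a stride-1 same
convolution is itself a convolution with the spatially flipped kernel, so
no scatter-add is needed. Computation is bit-deterministic given the seed.

Layout is NCHW. Layers cache what their backward pass needs during
``forward`` and are therefore single-use per pass, which suits the static
U-Net++ graph below.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D:
    """3×3 (or 1×1) convolution, stride 1, same padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        assert k in (1, 3)
        self.k = k
        self.W = Param(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.b = Param(np.zeros(cout))
        self._win = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.k == 1:
            self._win = x
            out = np.tensordot(x, self.W.value[:, :, 0, 0], axes=([1], [1]))
            return out.transpose(0, 3, 1, 2) + self.b.value[None, :, None, None]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
        self._win = win
        out = np.tensordot(win, self.W.value, axes=([1, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]

    def backward(self, d: np.ndarray) -> np.ndarray:
        self.b.grad += d.sum(axis=(0, 2, 3))
        if self.k == 1:
            x = self._win
            self.W.grad[:, :, 0, 0] += np.tensordot(d, x, axes=([0, 2, 3], [0, 2, 3]))
            return np.tensordot(d, self.W.value[:, :, 0, 0], axes=([1], [0])).transpose(0, 3, 1, 2)
        win = self._win
        self.W.grad += np.tensordot(d, win, axes=([0, 2, 3], [0, 2, 3]))
        dp = np.pad(d, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dwin = sliding_window_view(dp, (3, 3), axis=(2, 3))
        wflip = self.W.value[:, :, ::-1, ::-1]
        dx = np.tensordot(dwin, wflip, axes=([1, 4, 5], [0, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class BatchNorm2D:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(DTYPE)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, d: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self.gamma.grad += (d * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += d.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] / std[None, :, None, None]
        m = d.mean(axis=(0, 2, 3))[None, :, None, None]
        mx = (d * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (d - m - xhat * mx)


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, d: np.ndarray) -> np.ndarray:
        return d * self._mask


class ConvBlock:
    """Two consecutive 3×3 convolutions, each batch-normalized + ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, batch_norm: bool = True):
        self.conv1 = Conv2D(cin, cout, 3, rng)
        self.conv2 = Conv2D(cout, cout, 3, rng)
        self.bn1 = BatchNorm2D(cout) if batch_norm else None
        self.bn2 = BatchNorm2D(cout) if batch_norm else None
        self.relu1, self.relu2 = ReLU(), ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        for bn in (self.bn1, self.bn2):
            if bn is not None:
                ps += bn.params()
        return ps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x)
        if self.bn1 is not None:
            h = self.bn1.forward(h, train)
        h = self.relu1.forward(h)
        h = self.conv2.forward(h)
        if self.bn2 is not None:
            h = self.bn2.forward(h, train)
        return self.relu2.forward(h)

    def backward(self, d: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(d)
        if self.bn2 is not None:
            d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        if self.bn1 is not None:
            d = self.bn1.backward(d)
        return self.conv1.backward(d)


class MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, d: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=d.dtype)
        np.put_along_axis(out, self._idx[..., None], d[..., None], axis=-1)
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2:
    """2× nearest-neighbor upsampling; backward sums each 2×2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, d: np.ndarray) -> np.ndarray:
        n, c, h, w = d.shape
        return d.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class UNetPP:
    """Nested U-Net (U-Net++) with dense skip pathways.

    Node ``X[i, j]`` (``i`` = pooling level, ``j`` = skip-pathway column,
    ``i + j <= depth − 1``) receives the 2×-upsampled ``X[i+1, j−1]``
    concatenated with all same-level predecessors ``X[i, k], k < j``.
    Filters double along the encoder and halve along the decoder; the
    head is a 1×1 convolution + sigmoid on ``X[0, depth−1]``.
    """

    def __init__(self, depth: int = 4, base_filters: int = 32, in_channels: int = 1,
                 batch_norm: bool = True, rng_seed: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.batch_norm = batch_norm
        rng = np.random.default_rng(rng_seed)
        f = [base_filters * 2**i for i in range(depth)]
        self.filters = f
        self.blocks: dict[tuple[int, int], ConvBlock] = {}
        for i in range(depth):
            cin = in_channels if i == 0 else f[i - 1]
            self.blocks[(i, 0)] = ConvBlock(cin, f[i], rng, batch_norm)
        for j in range(1, depth):
            for i in range(depth - j):
                cin = j * f[i] + f[i + 1]
                self.blocks[(i, j)] = ConvBlock(cin, f[i], rng, batch_norm)
        self.head = Conv2D(f[0], 1, 1, rng)
        self.pools = {i: MaxPool2() for i in range(1, depth)}
        self.ups = {(i, j): Upsample2() for j in range(1, depth) for i in range(depth - j)}
        self._order = [(i, 0) for i in range(depth)] + [
            (i, j) for j in range(1, depth) for i in range(depth - j)
        ]

    def params(self):
        ps = []
        for key in self._order:
            ps += self.blocks[key].params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return logits of shape (N, 1, H, W)."""
        x = x.astype(DTYPE)
        d = self.depth
        act: dict[tuple[int, int], np.ndarray] = {}
        act[(0, 0)] = self.blocks[(0, 0)].forward(x, train)
        for i in range(1, d):
            act[(i, 0)] = self.blocks[(i, 0)].forward(self.pools[i].forward(act[(i - 1, 0)]), train)
        for j in range(1, d):
            for i in range(d - j):
                up = self.ups[(i, j)].forward(act[(i + 1, j - 1)])
                inp = np.concatenate([act[(i, k)] for k in range(j)] + [up], axis=1)
                act[(i, j)] = self.blocks[(i, j)].forward(inp, train)
        self._act_shapes = {k: v.shape for k, v in act.items()}
        return self.head.forward(act[(0, d - 1)])

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        d = self.depth
        f = self.filters
        grads: dict[tuple[int, int], np.ndarray] = {}
        grads[(0, d - 1)] = self.head.backward(dlogits.astype(DTYPE))
        for j in range(d - 1, 0, -1):
            for i in range(d - j - 1, -1, -1):
                dinp = self.blocks[(i, j)].backward(grads[(i, j)])
                splits = np.cumsum([f[i]] * j)
                parts = np.split(dinp, splits, axis=1)
                for k in range(j):
                    key = (i, k)
                    grads[key] = grads.get(key, 0) + parts[k]
                dup = self.ups[(i, j)].backward(parts[j])
                key = (i + 1, j - 1)
                grads[key] = grads.get(key, 0) + dup
        for i in range(d - 1, 0, -1):
            dx = self.blocks[(i, 0)].backward(grads[(i, 0)])
            dpool = self.pools[i].backward(dx)
            grads[(i - 1, 0)] = grads.get((i - 1, 0), 0) + dpool
        self.blocks[(0, 0)].backward(grads[(0, 0)])

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    # ---- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for idx, p in enumerate(self.params()):
            state[f"param_{idx}"] = p.value
        bn_idx = 0
        for key in self._order:
            blk = self.blocks[key]
            for bn in (blk.bn1, blk.bn2):
                if bn is not None:
                    state[f"bn_{bn_idx}_mean"] = bn.running_mean
                    state[f"bn_{bn_idx}_var"] = bn.running_var
                    bn_idx += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for idx, p in enumerate(self.params()):
            p.value = state[f"param_{idx}"].astype(DTYPE)
            p.grad = np.zeros_like(p.value)
        bn_idx = 0
        for key in self._order:
            blk = self.blocks[key]
            for bn in (blk.bn1, blk.bn2):
                if bn is not None:
                    bn.running_mean = state[f"bn_{bn_idx}_mean"].astype(DTYPE)
                    bn.running_var = state[f"bn_{bn_idx}_var"].astype(DTYPE)
                    bn_idx += 1


class PlainUNet:
    """Classic U-Net of the same depth/filters, for architecture comparison.

    The decoder node at level ``i`` sees only the encoder activation at
    level ``i`` plus the upsampled deeper decoder output — no nested
    intermediate nodes — so it has strictly fewer parameters than the
    nested variant at equal depth and base filters.
    """

    def __init__(self, depth: int = 4, base_filters: int = 32, in_channels: int = 1,
                 batch_norm: bool = True, rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        f = [base_filters * 2**i for i in range(depth)]
        self.depth = depth
        self.enc = []
        for i in range(depth):
            cin = in_channels if i == 0 else f[i - 1]
            self.enc.append(ConvBlock(cin, f[i], rng, batch_norm))
        self.dec = []
        for i in range(depth - 2, -1, -1):
            self.dec.append(ConvBlock(f[i] + f[i + 1], f[i], rng, batch_norm))
        self.head = Conv2D(f[0], 1, 1, rng)

    def params(self):
        ps = []
        for blk in self.enc + self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        acts = []
        h = x.astype(DTYPE)
        for i, blk in enumerate(self.enc):
            if i > 0:
                h = MaxPool2().forward(h)
            h = blk.forward(h, train)
            acts.append(h)
        for step, blk in enumerate(self.dec):
            i = self.depth - 2 - step
            h = np.concatenate([acts[i], Upsample2().forward(h)], axis=1)
            h = blk.forward(h, train)
        return self.head.forward(h)


class RMSprop:
    """RMSprop with decay 0.9, the optimizer used to train the segmenter."""

    def __init__(self, params: list[Param], lr: float = 1e-4, rho: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, c in zip(self.params, self.cache):
            c *= self.rho
            c += (1 - self.rho) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(c) + self.eps)
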