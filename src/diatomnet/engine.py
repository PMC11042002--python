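"""Self-contained numpy CNN engine: layer forward/backward kernels.

Tensors are ``(N, H, W, C)`` float32 arrays (channels last, so the innermost
axis of every column copy and GEMM is contiguous).  Convolutions run through
an im2col + GEMM path whose column buffers are filled one kernel offset at a
time (each fill is a contiguous-tail strided copy) and reused between
batches; 1x1 stride-1 convolutions skip the column copy entirely.  Max
pooling keeps a running maximum and a per-window offset index, so both
directions are a handful of strided passes; the cross-channel normalization
and its gradient use cumulative sums along the channel axis.

Every layer exposes

* ``forward(x, training=False) -> y`` caching whatever backward needs,
* ``backward(dy) -> dx`` accumulating parameter gradients in ``.grads``,
* ``params`` / ``grads``: dicts mapping parameter names to arrays.

The engine is deliberately minimal — single device, SGD-class optimizers,
no autograd graph — but exact: every backward pass matches central finite
differences to first order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "MaxPool2d",
    "AvgPool2d",
    "CrossChannelNorm",
    "Dropout",
    "Linear",
    "Softmax",
    "InceptionModule",
    "softmax_probs",
    "softmax_cross_entropy",
]


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax for ``(N, C)`` logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax_probs(logits)
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return loss, grad


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with bias and optional fused ReLU.

    Weights are stored ``(kh, kw, c_in, c_out)`` to match the channels-last
    data layout.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kh: int,
        kw: int,
        stride: int = 1,
        pad: tuple[int, int] = (0, 0),
        relu: bool = True,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw = kh, kw
        self.stride = stride
        self.pad = pad
        self.relu = relu
        self.dtype = dtype
        self.compute_dx = True  # first-layer convs skip the input gradient
        self.params = {
            "W": np.zeros((kh, kw, c_in, c_out), dtype=dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._bufs: dict[tuple, dict] = {}
        self._cache = None

    @property
    def _is_pointwise(self) -> bool:
        return self.kh == 1 and self.kw == 1 and self.stride == 1 and self.pad == (0, 0)

    def _buffers(self, n: int, h: int, w: int) -> dict:
        key = (n, h, w)
        if key not in self._bufs:
            ph, pw = self.pad
            s = self.stride
            oh = (h + 2 * ph - self.kh) // s + 1
            ow = (w + 2 * pw - self.kw) // s + 1
            buf = {"oh": oh, "ow": ow}
            if not self._is_pointwise:
                buf["xp"] = np.empty((n, h + 2 * ph, w + 2 * pw, self.c_in), dtype=self.dtype)
                buf["cols"] = np.empty(
                    (n, oh, ow, self.kh, self.kw, self.c_in), dtype=self.dtype
                )
            if len(self._bufs) > 3:  # keep a small working set of batch geometries
                self._bufs.clear()
            self._bufs[key] = buf
        return self._bufs[key]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv2d expected {self.c_in} input channels, got {c}")
        s = self.stride
        wmat = self.params["W"].reshape(-1, self.c_out)
        if self._is_pointwise:
            oh, ow = h, w
            cols2d = x.reshape(-1, c)
        else:
            buf = self._buffers(n, h, w)
            oh, ow = buf["oh"], buf["ow"]
            ph, pw = self.pad
            xp, cols = buf["xp"], buf["cols"]
            if ph or pw:
                xp[:] = 0.0
                xp[:, ph : ph + h, pw : pw + w, :] = x
            else:
                xp[...] = x
            # row-window fill: one copy per kernel row, with contiguous
            # (kw * c)-length runs on both sides of the assignment
            hp, wp = xp.shape[1], xp.shape[2]
            xr = xp.reshape(n, hp, wp * c)
            win = np.lib.stride_tricks.sliding_window_view(xr, self.kw * c, axis=2)
            crow = cols.reshape(n, oh, ow, self.kh, self.kw * c)
            for i in range(self.kh):
                crow[:, :, :, i, :] = win[:, i : i + s * oh : s, :: s * c, :][:, :, :ow, :]
            cols2d = cols.reshape(-1, self.kh * self.kw * c)
        y = np.empty((n, oh, ow, self.c_out), dtype=self.dtype)
        np.matmul(cols2d, wmat, out=y.reshape(-1, self.c_out))
        y += self.params["b"]
        if self.relu:
            np.maximum(y, 0.0, out=y)
        self._cache = (x if self._is_pointwise else None, (n, h, w, oh, ow), y if self.relu else None)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_pw, (n, h, w, oh, ow), y_relu = self._cache
        if self.relu:
            dy = np.where(y_relu > 0, dy, 0.0)
        dy2d = dy.reshape(-1, self.c_out)
        wmat = self.params["W"].reshape(-1, self.c_out)
        self.grads["b"] += dy2d.sum(axis=0)
        if self._is_pointwise:
            cols2d = x_pw.reshape(-1, self.c_in)
            self.grads["W"] += (cols2d.T @ dy2d).reshape(self.params["W"].shape)
            dx = (dy2d @ wmat.T).reshape(n, h, w, self.c_in)
            return dx
        buf = self._buffers(n, h, w)
        cols = buf["cols"]
        cols2d = cols.reshape(-1, self.kh * self.kw * self.c_in)
        self.grads["W"] += (cols2d.T @ dy2d).reshape(self.params["W"].shape)
        if not self.compute_dx:
            return None
        # cols are no longer needed: reuse the buffer for the column gradients
        np.matmul(dy2d, wmat.T, out=cols2d)
        ph, pw = self.pad
        s = self.stride
        dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, self.c_in), dtype=dy.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += cols[:, :, :, i, j, :]
        if ph or pw:
            return dxp[:, ph : ph + h, pw : pw + w, :]
        return dxp


def _ceil_pool_dim(d: int, k: int, s: int) -> int:
    return (-((d - k) // -s) + 1) if d > k else 1


class MaxPool2d(Layer):
    """Max pooling; ``ceil_mode`` clips edge windows, ``same`` pads for stride 1.

    The forward pass keeps a running maximum over the ``k*k`` window offsets
    and records the winning offset (first maximum wins on ties); backward
    routes each gradient to exactly that offset.
    """

    def __init__(self, k: int, stride: int, ceil_mode: bool = True, same: bool = False):
        super().__init__()
        self.k, self.stride = k, stride
        self.ceil_mode = ceil_mode
        self.same = same
        self._cache = None
        self._bufs: dict[tuple, dict] = {}

    def _geometry(self, h: int, w: int) -> tuple[int, int, int, int, int, int]:
        k, s = self.k, self.stride
        if self.same:
            p = k // 2
            oh = (h + 2 * p - k) // s + 1
            ow = (w + 2 * p - k) // s + 1
            pt = pl = p
        else:
            pt = pl = 0
            if self.ceil_mode:
                oh, ow = _ceil_pool_dim(h, k, s), _ceil_pool_dim(w, k, s)
            else:
                oh, ow = (h - k) // s + 1, (w - k) // s + 1
        hp = max(h + pt, (oh - 1) * s + k)
        wp = max(w + pl, (ow - 1) * s + k)
        return oh, ow, pt, pl, hp, wp

    def _pad_buffer(self, n: int, hp: int, wp: int, c: int, dtype) -> np.ndarray:
        key = (n, hp, wp, c)
        if key not in self._bufs:
            if len(self._bufs) > 3:
                self._bufs.clear()
            self._bufs[key] = np.full((n, hp, wp, c), -np.inf, dtype=dtype)
        return self._bufs[key]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        oh, ow, pt, pl, hp, wp = self._geometry(h, w)
        xp = self._pad_buffer(n, hp, wp, c, x.dtype)  # border strips stay -inf
        xp[:, pt : pt + h, pl : pl + w, :] = x
        y = np.empty((n, oh, ow, c), dtype=x.dtype)
        arg = np.zeros((n, oh, ow, c), dtype=np.uint8)
        if s > 1:
            phases = [
                [np.ascontiguousarray(xp[:, a::s, b::s, :]) for b in range(s)]
                for a in range(s)
            ]
        for o in range(k * k):
            i, j = o // k, o % k
            if s > 1:
                v = phases[i % s][j % s][:, i // s : i // s + oh, j // s : j // s + ow, :]
            else:
                v = xp[:, i : i + oh, j : j + ow, :]
            if o == 0:
                y[...] = v
            else:
                m = v > y
                np.copyto(y, v, where=m)
                np.copyto(arg, np.uint8(o), where=m)
        self._cache = (arg, (n, h, w, c, oh, ow, pt, pl, hp, wp))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, (n, h, w, c, oh, ow, pt, pl, hp, wp) = self._cache
        k, s = self.k, self.stride
        dxp = np.zeros((n, hp, wp, c), dtype=dy.dtype)
        for o in range(k * k):
            i, j = o // k, o % k
            dxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += dy * (arg == o)
        return dxp[:, pt : pt + h, pl : pl + w, :]


class AvgPool2d(Layer):
    """Average pooling, floor mode, no padding."""

    def __init__(self, kh: int, kw: int, stride: int = 1):
        super().__init__()
        self.kh, self.kw, self.stride = kh, kw, stride
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        s = self.stride
        oh = (h - self.kh) // s + 1
        ow = (w - self.kw) // s + 1
        y = np.zeros((n, oh, ow, c), dtype=x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                y += x[:, i : i + s * oh : s, j : j + s * ow : s, :]
        y /= self.kh * self.kw
        self._cache = (n, h, w, c, oh, ow)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c, oh, ow = self._cache
        s = self.stride
        g = dy / (self.kh * self.kw)
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i : i + s * oh : s, j : j + s * ow : s, :] += g
        return dx


class CrossChannelNorm(Layer):
    """Local response normalization across channels (parameter-free).

    ``y_c = x_c / (k + alpha/n * sum_{c' in window} x_{c'}^2)^beta`` with a
    centered window of ``n`` channels, clipped at the channel borders.
    """

    def __init__(self, window: int = 5, k: float = 2.0, alpha: float = 1e-4, beta: float = 0.75):
        super().__init__()
        self.n, self.k, self.alpha, self.beta = window, k, alpha, beta
        self._cache = None

    def _window_sum(self, t: np.ndarray) -> np.ndarray:
        c = t.shape[-1]
        half = self.n // 2
        cs = np.concatenate([np.zeros_like(t[..., :1]), np.cumsum(t, axis=-1)], axis=-1)
        hi = np.minimum(np.arange(c) + half + 1, c)
        lo = np.maximum(np.arange(c) - half, 0)
        return cs[..., hi] - cs[..., lo]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        ssum = self._window_sum(x * x)
        d = self.k + (self.alpha / self.n) * ssum
        dpow = d ** (-self.beta)
        y = x * dpow
        self._cache = (x, d, dpow)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, d, dpow = self._cache
        t = dy * x * dpow / d  # dy * x * d^(-beta-1)
        tsum = self._window_sum(t)
        return dy * dpow - (2.0 * self.alpha * self.beta / self.n) * x * tsum


class Dropout(Layer):
    """Inverted dropout; active only in training mode, identity otherwise."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self.rng: np.random.Generator = np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Linear(Layer):
    """Dense layer on flattened input; no activation (feeds softmax)."""

    def __init__(self, c_in: int, c_out: int, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": np.zeros((c_out, c_in), dtype=dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n = x.shape[0]
        xf = x.reshape(n, -1)
        if xf.shape[1] != self.c_in:
            raise ValueError(f"Linear expected {self.c_in} inputs, got {xf.shape[1]}")
        self._cache = (xf, x.shape)
        return xf @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, xshape = self._cache
        self.grads["W"] += dy.T @ xf
        self.grads["b"] += dy.sum(axis=0)
        return (dy @ self.params["W"]).reshape(xshape)


class Softmax(Layer):
    """Softmax over the class axis of ``(N, C)`` inputs."""

    def __init__(self):
        super().__init__()
        self._p = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n = x.shape[0]
        self._p = softmax_probs(x.reshape(n, -1))
        return self._p

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self._p
        return p * (dy - (dy * p).sum(axis=1, keepdims=True))


class InceptionModule(Layer):
    """Dimension-reduced inception block: four parallel branches, concatenated.

    Branches: 1x1; 1x1 reduce -> 3x3 (same); 1x1 reduce -> 5x5 (same);
    3x3/1 same max pool -> 1x1 projection.  All convolutions ReLU + bias.
    """

    def __init__(self, c_in: int, cfg, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        self.b1 = Conv2d(c_in, cfg.one_by_one, 1, 1, dtype=dtype)
        self.b2_reduce = Conv2d(c_in, cfg.three_reduce, 1, 1, dtype=dtype)
        self.b2 = Conv2d(cfg.three_reduce, cfg.three_by_three, 3, 3, pad=(1, 1), dtype=dtype)
        self.b3_reduce = Conv2d(c_in, cfg.five_reduce, 1, 1, dtype=dtype)
        self.b3 = Conv2d(cfg.five_reduce, cfg.five_by_five, 5, 5, pad=(2, 2), dtype=dtype)
        self.b4_pool = MaxPool2d(3, 1, same=True)
        self.b4 = Conv2d(c_in, cfg.pool_proj, 1, 1, dtype=dtype)
        self._subs = {
            "b1": self.b1,
            "b2_reduce": self.b2_reduce,
            "b2": self.b2,
            "b3_reduce": self.b3_reduce,
            "b3": self.b3,
            "b4": self.b4,
        }
        self.params = {
            f"{name}.{k}": v for name, sub in self._subs.items() for k, v in sub.params.items()
        }
        self.grads = {
            f"{name}.{k}": v for name, sub in self._subs.items() for k, v in sub.grads.items()
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y1 = self.b1.forward(x, training)
        y2 = self.b2.forward(self.b2_reduce.forward(x, training), training)
        y3 = self.b3.forward(self.b3_reduce.forward(x, training), training)
        y4 = self.b4.forward(self.b4_pool.forward(x, training), training)
        return np.concatenate([y1, y2, y3, y4], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c1 = self.cfg.one_by_one
        c2 = c1 + self.cfg.three_by_three
        c3 = c2 + self.cfg.five_by_five
        dx = self.b1.backward(np.ascontiguousarray(dy[..., :c1]))
        dx += self.b2_reduce.backward(self.b2.backward(np.ascontiguousarray(dy[..., c1:c2])))
        dx += self.b3_reduce.backward(self.b3.backward(np.ascontiguousarray(dy[..., c2:c3])))
        dx += self.b4_pool.backward(self.b4.backward(np.ascontiguousarray(dy[..., c3:])))
        return dx

    def zero_grads(self) -> None:
        for sub in self._subs.values():
            sub.zero_grads()
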