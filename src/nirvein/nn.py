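"""Minimal CPU neural-network layer stack with manual backpropagation.

Implements exactly the pieces the segmentation module needs — 2-D
convolution (im2col + BLAS matmul), batch normalization, ReLU, max
pooling, nearest-neighbor upsampling, linear layers and Adam — in
float32 numpy.  Layers follow a simple forward/backward contract:
``forward`` caches what ``backward`` needs; ``backward`` accumulates
parameter gradients and returns the gradient w.r.t. its input.
Parameters are named so state dicts can be saved, loaded and
transferred between architectures that share submodule names.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: children and params are discovered from attributes."""

    def named_params(self, prefix: str = "") -> list[tuple[str, Param]]:
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Param):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_params(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_params(f"{key}.{i}."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if name.startswith("run_") and isinstance(val, np.ndarray):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_buffers(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_buffers(f"{key}.{i}."))
        return out

    def params(self) -> list[Param]:
        return [p for _, p in self.named_params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data.copy() for k, p in self.named_params()}
        d.update({k: b.copy() for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray], strict: bool = True) -> None:
        params = dict(self.named_params())
        buffers = dict(self.named_buffers())
        for k, v in d.items():
            if k in params:
                if params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {params[k].data.shape} vs {v.shape}")
                params[k].data[...] = v
            elif k in buffers:
                buffers[k][...] = v
            elif strict:
                raise KeyError(f"unexpected parameter {k}")

    def set_train(self, mode: bool) -> None:
        self.training = mode
        for name, val in vars(self).items():
            if isinstance(val, Module):
                val.set_train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.set_train(mode)

    training = True


class Conv2d(Module):
    """2-D convolution, NCHW interface, internally NHWC tap-wise GEMMs.

    Each kernel tap (i, j) contributes one (N*OH*OW, Cin) x (Cin, Cout)
    matmul on a shifted view of the padded input, which keeps the data
    movement cache-friendly on CPU instead of materializing a full
    im2col buffer.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        std = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU nets
        self.weight = Param(rng.normal(0.0, std, (k, k, cin, cout)))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xh = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # NHWC
        xp = np.pad(xh, ((0, 0), (p, p), (p, p), (0, 0))) if p else xh
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        W = self.weight.data
        if c <= 4 < k * k:
            # few input channels (e.g. the grayscale stem): one big GEMM on
            # an im2col buffer beats k*k nearly rank-deficient updates
            view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            cols = np.ascontiguousarray(view[:, ::s, ::s]).reshape(n * oh * ow, c * k * k)
            # view layout (..., C, k, k) -> weight as (C, k, k, Cout)
            wmat = W.transpose(2, 0, 1, 3).reshape(c * k * k, self.cout)
            out = cols @ wmat
            self._cache = ("im2col", cols, x.shape, oh, ow)
        else:
            out = np.zeros((n * oh * ow, self.cout), dtype=F32)
            taps = []
            for i in range(k):
                for j in range(k):
                    sl = np.ascontiguousarray(
                        xp[:, i : i + s * oh : s, j : j + s * ow : s, :]
                    ).reshape(-1, c)
                    out += sl @ W[i, j]
                    taps.append(sl)
            self._cache = ("taps", taps, x.shape, oh, ow)
        return np.ascontiguousarray(
            out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, g: np.ndarray) -> np.ndarray:
        kind, data, xshape, oh, ow = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        W = self.weight.data
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=F32)
        if kind == "im2col":
            cols = data
            dw = (cols.T @ g2).reshape(c, k, k, self.cout).transpose(1, 2, 0, 3)
            self.weight.grad += dw
            wmat = W.transpose(2, 0, 1, 3).reshape(c * k * k, self.cout)
            dcols = (g2 @ wmat.T).reshape(n, oh, ow, c, k, k)
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += dcols[..., i, j]
        else:
            for i in range(k):
                for j in range(k):
                    self.weight.grad[i, j] += data[i * k + j].T @ g2
                    dxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += (
                        g2 @ W[i, j].T
                    ).reshape(n, oh, ow, c)
        if p:
            dxp = dxp[:, p : p + h, p : p + w, :]
        return np.ascontiguousarray(dxp.transpose(0, 3, 1, 2))


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.size / x.shape[1]
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var * m / max(m - 1, 1) - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape)
        return (self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)).astype(F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        m = g.size / g.shape[1]
        self.gamma.grad += np.sum(g * xhat, axis=axes)
        self.beta.grad += np.sum(g, axis=axes)
        gg = g * self.gamma.data.reshape(shape)
        if not self.training:
            return (gg * inv.reshape(shape)).astype(F32)
        dx = (
            gg - gg.mean(axis=axes).reshape(shape) - xhat * (gg * xhat).mean(axis=axes).reshape(shape)
        ) * inv.reshape(shape)
        return dx.astype(F32)


BatchNorm1d = BatchNorm2d  # same math; axes are picked from ndim


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0).astype(F32)


class MaxPool2d(Module):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n_, c_, oh, ow = view.shape[:4]
        flat = view.reshape(n, c, oh, ow, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape, (oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        arg, xshape, (oh, ow) = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        hp, wp = h + 2 * p, w + 2 * p
        dxp = np.zeros((n, c, hp * wp), dtype=F32)
        rows = (np.arange(oh) * s)[None, None, :, None] + (arg // k)
        cols = (np.arange(ow) * s)[None, None, None, :] + (arg % k)
        flat_idx = (rows * wp + cols).reshape(n, c, -1)
        np.add.at(dxp, (np.arange(n)[:, None, None], np.arange(c)[None, :, None], flat_idx),
                  g.reshape(n, c, -1))
        dxp = dxp.reshape(n, c, hp, wp)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class UpsampleNearest2(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(F32)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, (cout, cin)))
        self.bias = Param(np.zeros(cout))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.weight.grad += g.T @ self._x
        self.bias.grad += g.sum(axis=0)
        return (g @ self.weight.data).astype(F32)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Adam:
    """Adam with decoupled parameter list; deterministic given the grads."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
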