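"""Convolutional layers with explicit forward/backward passes.

Convolutions are lowered to matrix multiplication with im2col (a k*k
slicing loop, no Python per-pixel work); transposed convolutions reuse the
same machinery through the conv/conv-transpose duality (the forward pass
of one is the data-backward pass of the other).  All layers cache what
their backward pass needs and accumulate parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np


def _pair_out(h: int, w: int, k: int, s: int, p: int) -> tuple[int, int]:
    return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1


def im2col(x: np.ndarray, k: int, s: int, p: int) -> tuple[np.ndarray, tuple]:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix.

    The (C, k, k) leading layout makes the reshape a view, so the only
    copy is the strided gather itself.
    """
    n, c, h, w = x.shape
    ho, wo = _pair_out(h, w, k, s, p)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(n, c * k * k, ho * wo), (n, c, h, w, ho, wo)


def col2im(mat: np.ndarray, shape_info: tuple, k: int, s: int, p: int) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col` (same (N, C*k*k, Ho*Wo) layout)."""
    n, c, h, w, ho, wo = shape_info
    cols = mat.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=mat.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + s * ho : s, j : j + s * wo : s] += cols[:, :, i, j]
    return xp[:, :, p : p + h, p : p + w] if p else xp


class Layer:
    """Base: stateless unless it holds parameters."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """k x k convolution, stride s, zero padding p; weight (Cout, Cin, k, k)."""

    def __init__(self, cin, cout, k=4, s=2, p=1, rng=None, dtype=np.float32):
        super().__init__()
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, s, p
        rng = rng or np.random.default_rng(0)
        self.params = {
            "w": rng.normal(0.0, 0.02, (cout, cin, k, k)).astype(dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cache = None

    @property
    def kernel_stride(self) -> tuple[int, int]:
        return self.k, self.s

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, info = im2col(x, self.k, self.s, self.p)
        n, _, _, _, ho, wo = info
        wmat = self.params["w"].reshape(self.cout, -1).astype(cols.dtype)  # (Cout, Cin*k*k)
        y = np.matmul(wmat, cols)  # (N, Cout, Ho*Wo)
        y += self.params["b"].astype(cols.dtype)[:, None]
        self._cache = (cols, info)
        return y.reshape(n, self.cout, ho, wo)

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        cols, info = self._cache
        n, c, h, w, ho, wo = info
        dyf = dy.reshape(n, self.cout, ho * wo)
        wmat = self.params["w"].reshape(self.cout, -1)
        if accumulate:
            self.grads["w"] += np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
                self.params["w"].shape
            )
            self.grads["b"] += dyf.sum(axis=(0, 2))
        dcols = np.matmul(wmat.T.astype(dyf.dtype), dyf)  # (N, Cin*k*k, Ho*Wo)
        return col2im(dcols, info, self.k, self.s, self.p)


class ConvTranspose2d(Layer):
    """Transposed k x k convolution, stride s, padding p; weight (Cin, Cout, k, k).

    Output size is (H-1)*s - 2p + k per side (the exact inverse of the
    matching Conv2d geometry); forward is implemented as the conv
    data-backward pass, backward-data as the conv forward pass.
    """

    def __init__(self, cin, cout, k=4, s=2, p=1, rng=None, dtype=np.float32):
        super().__init__()
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, s, p
        rng = rng or np.random.default_rng(0)
        self.params = {
            "w": rng.normal(0.0, 0.02, (cin, cout, k, k)).astype(dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, cin, h, w = x.shape
        ho = (h - 1) * self.s - 2 * self.p + self.k
        wo = (w - 1) * self.s - 2 * self.p + self.k
        xf = x.reshape(n, cin, h * w)
        wr = self.params["w"].reshape(cin, -1).astype(x.dtype)  # (Cin, Cout*k*k)
        dcols = np.matmul(wr.T, xf)  # (N, Cout*k*k, h*w)
        info = (n, self.cout, ho, wo, h, w)
        y = col2im(dcols, info, self.k, self.s, self.p)
        y += self.params["b"].astype(y.dtype)[None, :, None, None]
        self._cache = (xf, (n, h, w))
        return y

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        xf, (n, h, w) = self._cache
        cols, _ = im2col(dy, self.k, self.s, self.p)  # (N, Cout*k*k, h*w)
        if accumulate:
            self.grads["w"] += np.matmul(xf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
                self.params["w"].shape
            )
            self.grads["b"] += dy.sum(axis=(0, 2, 3))
        wr = self.params["w"].reshape(self.cin, -1).astype(cols.dtype)
        dx = np.matmul(wr, cols)  # (N, Cin, h*w)
        return dx.reshape(n, self.cin, h, w)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation over H x W, with affine scale/shift."""

    def __init__(self, c, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        g = self.params["gamma"].astype(x.dtype)[None, :, None, None]
        b = self.params["beta"].astype(x.dtype)[None, :, None, None]
        return g * xhat + b

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        xhat, inv = self._cache
        if accumulate:
            self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
            self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"].astype(dy.dtype)[None, :, None, None]
        dxhat = dy * g
        m = dxhat.mean(axis=(2, 3), keepdims=True)
        mx = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m - xhat * mx)


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy, accumulate=accumulate)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self, prefix: str = "") -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out.update(layer.named_params(f"{prefix}{i}."))
            else:
                for k, v in layer.params.items():
                    out[f"{prefix}{i}.{k}"] = v
        return out

    def named_grads(self, prefix: str = "") -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out.update(layer.named_grads(f"{prefix}{i}."))
            else:
                for k, v in layer.grads.items():
                    out[f"{prefix}{i}.{k}"] = v
        return out


class Adam:
    """Adam over a name -> array parameter dict (grads supplied alongside)."""

    def __init__(self, params: dict, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= (self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(
                p.dtype
            )

    def state_dict(self) -> dict:
        out = {"t": np.array(self.t)}
        for k in self.m:
            out[f"m.{k}"] = self.m[k]
            out[f"v.{k}"] = self.v[k]
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for k in self.m:
            self.m[k] = state[f"m.{k}"]
            self.v[k] = state[f"v.{k}"]
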