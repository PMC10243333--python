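"""Minimal NumPy convolutional-network engine.

Layers operate on ``(N, C, H, W)`` float arrays and implement explicit
``forward``/``backward`` passes (reverse-mode gradients derived by hand),
which keeps the whole training stack dependency-free, deterministic and
easy to verify by finite differences.  Provided building blocks: 2-D
convolution (zero-padded "same" at stride 1, halving at stride 2), batch
normalization with running statistics, ReLU, nearest-neighbour 2x
upsampling, sequential and residual composition, and an Adam optimizer.

Convolutions are evaluated as matrix products over sliding-window views,
so the heavy lifting stays inside BLAS.  Gradient conventions: calling
``backward(gy)`` after ``forward(x)`` accumulates parameter gradients in
``Param.grad`` and returns the gradient with respect to ``x``.  Each layer
caches its latest forward activations; a layer instance therefore appears
exactly once in a model graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "NearestUpsample2x",
    "Sequential",
    "Residual",
    "Adam",
]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: parameter/buffer bookkeeping shared by all layers."""

    def __init__(self):
        self._params: dict[str, Param] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = False

    # -- graph structure --------------------------------------------------
    def children(self) -> list[tuple[str, "Module"]]:
        return []

    def named_params(self, prefix: str = "") -> list[tuple[str, Param]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, child in self.children():
            out.extend(child.named_params(prefix + name + "."))
        return out

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_params()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # -- train/eval mode ---------------------------------------------------
    def train(self) -> "Module":
        self.training = True
        for _, c in self.children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, c in self.children():
            c.eval()
        return self

    # -- serialization -----------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        d = {prefix + n: p.value.copy() for n, p in self._params.items()}
        d.update({prefix + n: b.copy() for n, b in self._buffers.items()})
        for name, child in self.children():
            d.update(child.state_dict(prefix + name + "."))
        return d

    def load_state_dict(self, d: dict[str, np.ndarray], prefix: str = "") -> None:
        for n, p in self._params.items():
            p.value = np.array(d[prefix + n], dtype=float)
            p.grad = np.zeros_like(p.value)
        for n in self._buffers:
            self._buffers[n] = np.array(d[prefix + n], dtype=float)
        for name, child in self.children():
            child.load_state_dict(d, prefix + name + ".")

    # -- interface ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Module):
    """Zero-padded 2-D convolution (cross-correlation), stride 1 or 2.

    Stride 1 preserves spatial size for odd kernels; stride 2 halves even
    input sides.  Kaiming fan-in initialization.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        self._params["weight"] = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                                  size=(out_channels, in_channels, k, k)))
        self._params["bias"] = Param(np.zeros(out_channels))
        self.kernel_size = k
        self.stride = stride
        self.pad = k // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.pad
        w = self._params["weight"].value
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N, Ho, Wo, Cout)
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        y += self._params["bias"].value[None, :, None, None]
        self._cache = (xp, win, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.pad
        w = self._params["weight"].value
        xp, win, xshape = self._cache
        self._params["weight"].grad += np.tensordot(gy, win, axes=([0, 2, 3], [0, 2, 3]))
        self._params["bias"].grad += gy.sum(axis=(0, 2, 3))
        n, _, ho, wo = gy.shape
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                t = np.tensordot(gy, w[:, :, i, j], axes=([1], [0]))  # (N, Ho, Wo, Cin)
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += t.transpose(0, 3, 1, 2)
        h, wdt = xshape[2], xshape[3]
        return dxp[:, :, p : p + h, p : p + wdt]


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes with batch statistics and updates the running
    mean/variance (momentum 0.1); evaluation mode uses the frozen running
    statistics, so inference is deterministic and batch-independent.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self._params["gamma"] = Param(np.ones(channels))
        self._params["beta"] = Param(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: np.ndarray) -> np.ndarray:
        gamma = self._params["gamma"].value
        beta = self._params["beta"].value
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self._buffers["running_mean"] = (
                (1 - self.momentum) * self._buffers["running_mean"] + self.momentum * mean
            )
            self._buffers["running_var"] = (
                (1 - self.momentum) * self._buffers["running_var"] + self.momentum * var
            )
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, self.training)
        return gamma[None, :, None, None] * xhat + beta[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gamma = self._params["gamma"].value
        xhat, inv, was_training = self._cache
        self._params["gamma"].grad += (gy * xhat).sum(axis=(0, 2, 3))
        self._params["beta"].grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * gamma[None, :, None, None]
        if not was_training:
            return gxhat * inv[None, :, None, None]
        n, _, h, w = gy.shape
        m = n * h * w
        s1 = gxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * gxhat - s1 - xhat * s2)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class NearestUpsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling (backward sums 2x2 blocks)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        super().__init__()
        self.layers = layers

    def children(self):
        return [(str(i), layer) for i, layer in enumerate(self.layers)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Residual(Module):
    """y = shortcut(x) + sign * body(x).

    ``shortcut=None`` means identity; ``sign=-1`` gives the residual-
    subtraction form used by denoisers that predict the noise component.
    """

    def __init__(self, body: Module, shortcut: Module | None = None, sign: int = 1):
        super().__init__()
        self.body = body
        self.shortcut = shortcut
        self.sign = sign

    def children(self):
        out = [("body", self.body)]
        if self.shortcut is not None:
            out.append(("shortcut", self.shortcut))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        skip = x if self.shortcut is None else self.shortcut.forward(x)
        return skip + self.sign * self.body.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = self.body.backward(self.sign * gy)
        gx = gx + (gy if self.shortcut is None else self.shortcut.backward(gy))
        return gx


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
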