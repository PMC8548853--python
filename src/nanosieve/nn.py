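"""Minimal 1D convolutional network engine (forward + backprop) on numpy.

Implements exactly the layers the squiggle classifier needs — 1D
convolution (im2col/BLAS), batch normalization, ReLU, global average
pooling, a fully connected head — together with softmax cross-entropy and
Adam.  Activations are float32 and shaped (batch, channels, length).

Every layer exposes ``forward(x, training)`` and ``backward(gout)``;
``backward`` returns the gradient with respect to the layer input and
stores parameter gradients on the layer.  Backward through a layer whose
last forward ran in evaluation mode differentiates the evaluation-mode
function (batch norm becomes a fixed affine map), which is what
gradient-based attribution needs.
"""

from __future__ import annotations

import numpy as np

from nanosieve.errors import ValidationError

DTYPE = np.float32


class Layer:
    """Base layer: parameterless by default."""

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        return []

    def gradients(self) -> list[tuple[str, np.ndarray]]:
        return []

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def kaiming_fanout_std(out_channels: int, kernel: int) -> float:
    """He initialization scale in fan-out mode for a ReLU conv layer."""
    return float(np.sqrt(2.0 / (out_channels * kernel)))


class Conv1d(Layer):
    """1D convolution with 'same'-style padding (pad = kernel // 2), no bias.

    Bias is omitted because every convolution is followed by batch norm,
    whose shift parameter subsumes it.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        if kernel < 1 or stride < 1:
            raise ValidationError("kernel and stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        rng = rng if rng is not None else np.random.default_rng()
        std = kaiming_fanout_std(out_channels, kernel)
        self.weight = rng.normal(0.0, std,
                                 size=(out_channels, in_channels, kernel)).astype(DTYPE)
        self.gweight = np.zeros_like(self.weight)
        self._cache = None

    def out_length(self, length: int) -> int:
        return (length + 2 * self.pad - self.kernel) // self.stride + 1

    def parameters(self):
        return [("weight", self.weight)]

    def gradients(self):
        return [("weight", self.gweight)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        if C != self.in_channels:
            raise ValidationError(f"expected {self.in_channels} channels, got {C}")
        if self.pad:
            xp = np.zeros((B, C, L + 2 * self.pad), dtype=DTYPE)
            xp[:, :, self.pad:self.pad + L] = x
        else:
            xp = np.ascontiguousarray(x, dtype=DTYPE)
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        patches = windows[:, :, ::self.stride, :]            # (B, C, Lout, K)
        Lout = patches.shape[2]
        xcol = np.ascontiguousarray(patches.transpose(0, 2, 1, 3)).reshape(
            B * Lout, C * self.kernel)
        wmat = self.weight.reshape(self.out_channels, C * self.kernel)
        out = xcol @ wmat.T                                   # (B*Lout, O)
        self._cache = (xcol, (B, C, L, Lout))
        return out.reshape(B, Lout, self.out_channels).transpose(0, 2, 1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xcol, (B, C, L, Lout) = self._cache
        gmat = np.ascontiguousarray(gout.transpose(0, 2, 1)).reshape(
            B * Lout, self.out_channels)
        self.gweight = (gmat.T @ xcol).reshape(self.weight.shape)
        wmat = self.weight.reshape(self.out_channels, C * self.kernel)
        gcol = (gmat @ wmat).reshape(B, Lout, C, self.kernel).transpose(0, 2, 1, 3)
        gxp = np.zeros((B, C, L + 2 * self.pad), dtype=DTYPE)
        # per-tap scatter: within one k the strided targets are distinct
        starts = self.stride * np.arange(Lout)
        for k in range(self.kernel):
            gxp[:, :, starts + k] += gcol[:, :, :, k]
        return gxp[:, :, self.pad:self.pad + L] if self.pad else gxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = np.ones(channels, dtype=DTYPE)
        self.bias = np.zeros(channels, dtype=DTYPE)
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def parameters(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def gradients(self):
        return [("weight", self.gweight), ("bias", self.gbias)]

    def buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv.astype(DTYPE), training, x.shape)
        return (self.weight[None, :, None] * xhat
                + self.bias[None, :, None]).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, training, shape = self._cache
        self.gweight = (gout * xhat).sum(axis=(0, 2)).astype(DTYPE)
        self.gbias = gout.sum(axis=(0, 2)).astype(DTYPE)
        scale = (self.weight * inv)[None, :, None]
        if not training:
            return (gout * scale).astype(DTYPE)
        B, C, L = shape
        n = B * L
        gxhat = gout * self.weight[None, :, None]
        sum_g = gxhat.sum(axis=(0, 2), keepdims=True)
        sum_gx = (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv[None, :, None] * (gxhat - sum_g / n - xhat * sum_gx / n)
                ).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0).astype(DTYPE)


class GlobalAvgPool(Layer):
    """Mean over the time axis: (B, C, L) -> (B, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return (np.repeat(gout[:, :, None], self._L, axis=2) / self._L).astype(DTYPE)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        # fan-in scaling keeps initial logits near zero so softmax starts
        # close to uniform; Kaiming fan-out is reserved for the conv trunk
        std = float(np.sqrt(1.0 / in_features))
        self.weight = rng.normal(0.0, std, size=(out_features, in_features)).astype(DTYPE)
        self.bias = np.zeros(out_features, dtype=DTYPE)
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)

    def parameters(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def gradients(self):
        return [("weight", self.gweight), ("bias", self.gbias)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return (x @ self.weight.T + self.bias).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gweight = (gout.T @ self._x).astype(DTYPE)
        self.gbias = gout.sum(axis=0).astype(DTYPE)
        return (gout @ self.weight).astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient with respect to the logits."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(B), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(B), labels] -= 1.0
    return loss, (grad / B).astype(DTYPE)


class Adam:
    """Adam optimizer over a list of (layer, param-name) slots."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.slots = []
        for layer in layers:
            for (name, p), (_, g) in zip(layer.parameters(), layer.gradients()):
                self.slots.append((layer, name))
        self.m = {id_: np.zeros_like(self._get(*id_)) for id_ in self.slots}
        self.v = {id_: np.zeros_like(self._get(*id_)) for id_ in self.slots}

    @staticmethod
    def _get(layer: Layer, name: str) -> np.ndarray:
        return getattr(layer, name)

    @staticmethod
    def _get_grad(layer: Layer, name: str) -> np.ndarray:
        return getattr(layer, "g" + name)

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for slot in self.slots:
            layer, name = slot
            p = self._get(layer, name)
            g = self._get_grad(layer, name)
            m = self.m[slot] = self.b1 * self.m[slot] + (1 - self.b1) * g
            v = self.v[slot] = self.b2 * self.v[slot] + (1 - self.b2) * g * g
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(DTYPE)
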