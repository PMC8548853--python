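"""Compact 1D-ResNet bottleneck classifier for raw squiggle windows.

The architecture mirrors the first layer of a production basecaller but
with far fewer channels (a 20-channel stem instead of 512), followed by
four residual layers of two bottleneck units each.  Channel width grows
by a factor of 1.5 per layer (20, 30, 45, 68 after round-half-up) and
every bottleneck halves the time resolution with a stride of 2, so a
3000-sample window is reduced to a handful of positions before global
average pooling and a fully connected softmax head.  The whole default
model stores well under 304 KB of 32-bit parameters.

Each bottleneck is the classic reduce-transform-expand unit: a 1x1
convolution halving the channel count, a kernel-3 strided convolution,
and a 1x1 expansion back to the layer width, with batch norm + ReLU
inside and a strided 1x1 projection on the shortcut whenever the shape
changes.  Initialization is Kaiming fan-out, deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from nanosieve.errors import ValidationError
from nanosieve import nn
from nanosieve.nn import DTYPE

__all__ = ["ModelConfig", "Network", "build_model", "parameter_bytes",
           "integrated_gradients", "save_checkpoint", "load_checkpoint"]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults realize the reference architecture: 20-channel stem
    (kernel 19, stride 3), 4 layers x 2 bottleneck blocks, x1.5 channel
    growth, stride-2 blocks, 2 classes, 3000-sample input.
    """

    stem_channels: int = 20
    stem_kernel: int = 19
    stem_stride: int = 3
    n_layers: int = 4
    blocks_per_layer: int = 2
    channel_growth: float = 1.5
    block_stride: int = 2
    block_kernel: int = 3
    n_classes: int = 2
    input_length: int = 3000
    #: if False, only the first block of each layer strides
    stride_every_block: bool = True

    def layer_channels(self) -> list[int]:
        """Channel width per layer: round-half-up of stem * growth^i."""
        chans = [_round_half_up(self.stem_channels * self.channel_growth ** i)
                 for i in range(self.n_layers)]
        if any(b <= a for a, b in zip(chans, chans[1:])):
            raise ValidationError(f"channel schedule must strictly increase, got {chans}")
        return chans

    def total_stride(self) -> int:
        n_striding = (self.n_layers * self.blocks_per_layer
                      if self.stride_every_block else self.n_layers)
        return self.stem_stride * self.block_stride ** n_striding

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if min(self.stem_channels, self.stem_kernel, self.stem_stride,
               self.n_layers, self.blocks_per_layer, self.block_stride,
               self.block_kernel) < 1:
            raise ValidationError("all architecture sizes must be >= 1")
        if self.channel_growth <= 1.0:
            raise ValidationError("channel_growth must exceed 1")
        min_len = self.total_stride()
        if self.input_length < min_len:
            raise ValidationError(
                f"input_length {self.input_length} too short for the stride "
                f"pyramid; minimum is {min_len}")
        self.layer_channels()


class Bottleneck:
    """Residual bottleneck unit: 1x1 reduce -> k-wide strided conv -> 1x1 expand."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        mid = max(1, out_channels // 2)
        self.conv1 = nn.Conv1d(in_channels, mid, 1, 1, rng)
        self.bn1 = nn.BatchNorm1d(mid)
        self.conv2 = nn.Conv1d(mid, mid, kernel, stride, rng)
        self.bn2 = nn.BatchNorm1d(mid)
        self.conv3 = nn.Conv1d(mid, out_channels, 1, 1, rng)
        self.bn3 = nn.BatchNorm1d(out_channels)
        # zero gain on the residual branch's last norm: each block starts as
        # (a projection of) the identity, which stabilises short training runs
        self.bn3.weight[:] = 0.0
        self.relu1, self.relu2, self.relu_out = nn.ReLU(), nn.ReLU(), nn.ReLU()
        if stride != 1 or in_channels != out_channels:
            self.proj: nn.Conv1d | None = nn.Conv1d(in_channels, out_channels, 1,
                                                    stride, rng)
            self.proj_bn: nn.BatchNorm1d | None = nn.BatchNorm1d(out_channels)
        else:
            self.proj = None
            self.proj_bn = None

    def sublayers(self) -> list[tuple[str, nn.Layer]]:
        named = [("conv1", self.conv1), ("bn1", self.bn1),
                 ("conv2", self.conv2), ("bn2", self.bn2),
                 ("conv3", self.conv3), ("bn3", self.bn3)]
        if self.proj is not None:
            named += [("proj", self.proj), ("proj_bn", self.proj_bn)]
        return named

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        out = self.relu2.forward(self.bn2.forward(self.conv2.forward(out, training), training), training)
        out = self.bn3.forward(self.conv3.forward(out, training), training)
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            shortcut = x
        return self.relu_out.forward(out + shortcut, training)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gout)
        gmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(g))))))))
        if self.proj is not None:
            gshort = self.proj.backward(self.proj_bn.backward(g))
        else:
            gshort = g
        return gmain + gshort


class Network:
    """Realized classifier: stem -> bottleneck layers -> pool -> softmax head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        chans = config.layer_channels()

        self.stem = nn.Conv1d(1, config.stem_channels, config.stem_kernel,
                              config.stem_stride, rng)
        self.stem_bn = nn.BatchNorm1d(config.stem_channels)
        self.stem_relu = nn.ReLU()

        self.blocks: list[tuple[str, Bottleneck]] = []
        in_ch = config.stem_channels
        for li, out_ch in enumerate(chans):
            for bi in range(config.blocks_per_layer):
                strides = (config.block_stride if config.stride_every_block
                           or bi == 0 else 1)
                blk = Bottleneck(in_ch, out_ch, config.block_kernel, strides, rng)
                self.blocks.append((f"layer{li + 1}.block{bi + 1}", blk))
                in_ch = out_ch

        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_ch, config.n_classes, rng)

    # ------------------------------------------------------------------ plumbing
    def _named_layers(self) -> list[tuple[str, nn.Layer]]:
        named: list[tuple[str, nn.Layer]] = [("stem", self.stem),
                                             ("stem_bn", self.stem_bn)]
        for prefix, blk in self.blocks:
            named += [(f"{prefix}.{n}", l) for n, l in blk.sublayers()]
        named.append(("fc", self.fc))
        return named

    def parameter_inventory(self) -> list[tuple[str, tuple[int, ...]]]:
        """All stored tensors (trainable + batch-norm running stats) and shapes."""
        inv = []
        for lname, layer in self._named_layers():
            for pname, p in layer.parameters():
                inv.append((f"{lname}.{pname}", p.shape))
            for bname, b in layer.buffers():
                inv.append((f"{lname}.{bname}", b.shape))
        return inv

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for lname, layer in self._named_layers():
            for pname, p in layer.parameters():
                state[f"{lname}.{pname}"] = p
            for bname, b in layer.buffers():
                state[f"{lname}.{bname}"] = b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise ValidationError(f"checkpoint missing tensors: {sorted(missing)[:5]}")
        for lname, layer in self._named_layers():
            for pname, _ in layer.parameters():
                setattr(layer, pname, state[f"{lname}.{pname}"].astype(DTYPE).copy())
            for bname, _ in layer.buffers():
                setattr(layer, bname, state[f"{lname}.{bname}"].astype(DTYPE).copy())
            # re-zero gradient slots to match the loaded shapes
            for gname, _ in layer.gradients():
                setattr(layer, "g" + gname, np.zeros_like(getattr(layer, gname)))

    def trainable_layers(self) -> list[nn.Layer]:
        return [layer for _, layer in self._named_layers()]

    # ------------------------------------------------------------------ compute
    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 1:
            x = x[None, None, :]
        elif x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.config.input_length:
            raise ValidationError(
                f"window length {x.shape[2]} != input_length {self.config.input_length}")
        return x

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Pre-softmax class scores, shape (batch, n_classes)."""
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(self._as_batch(x), training),
                                 training), training)
        for _, blk in self.blocks:
            h = blk.forward(h, training)
        return self.fc.forward(self.pool.forward(h, training), training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities on the simplex, shape (batch, n_classes)."""
        return nn.softmax(self.logits(x, training).astype(np.float64))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop from logit gradients to the input; fills parameter grads."""
        g = self.pool.backward(self.fc.backward(dlogits.astype(DTYPE)))
        for _, blk in reversed(self.blocks):
            g = blk.backward(g)
        return self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    def trunk_output_length(self, input_length: int | None = None) -> int:
        """Time positions left after the convolutional trunk (analytic)."""
        L = self.config.input_length if input_length is None else input_length
        L = self.stem.out_length(L)
        for _, blk in self.blocks:
            L = blk.conv2.out_length(L)
        return L


def build_model(config: ModelConfig | None = None, seed: int = 0) -> Network:
    """Instantiate the classifier with Kaiming fan-out init, seeded."""
    return Network(config if config is not None else ModelConfig(), seed=seed)


def parameter_bytes(network: Network) -> int:
    """Serialized 32-bit storage: 4 bytes per scalar, batch-norm state included."""
    return 4 * sum(int(np.prod(shape)) for _, shape in network.parameter_inventory())


def forward(network: Network, windows: np.ndarray) -> np.ndarray:
    """Evaluation-mode class probabilities for a batch of windows."""
    return network.forward(windows, training=False)


def integrated_gradients(network: Network, window: np.ndarray,
                         baseline: np.ndarray | None = None, steps: int = 64,
                         target_class: int = 1) -> np.ndarray:
    """Integrated-gradients attribution of the target-class logit.

    Approximates the path integral of the input gradient along the
    straight line from ``baseline`` (default: all zeros) to ``window``
    with a midpoint Riemann sum, and multiplies by the displacement.  The
    completeness identity sum(attributions) ~= score(window) -
    score(baseline) holds to the quadrature error.
    """
    window = np.asarray(window, dtype=np.float64).ravel()
    if baseline is None:
        baseline = np.zeros_like(window)
    baseline = np.asarray(baseline, dtype=np.float64).ravel()
    if window.shape != baseline.shape:
        raise ValidationError(
            f"window length {window.size} != baseline length {baseline.size}")
    if steps < 1:
        raise ValidationError(f"steps must be >= 1, got {steps}")
    if not 0 <= target_class < network.config.n_classes:
        raise ValidationError(f"target_class {target_class} out of range")

    alphas = (np.arange(steps) + 0.5) / steps
    points = baseline[None, :] + alphas[:, None] * (window - baseline)[None, :]
    network.logits(points.astype(DTYPE), training=False)
    dlogits = np.zeros((steps, network.config.n_classes), dtype=DTYPE)
    dlogits[:, target_class] = 1.0
    grads = network.backward(dlogits)[:, 0, :].astype(np.float64)
    return (window - baseline) * grads.mean(axis=0)


def save_checkpoint(network: Network, path: str | Path) -> Path:
    """Single-file checkpoint: named tensors + the config as embedded JSON."""
    path = Path(path)
    meta = json.dumps({"config": asdict(network.config), "seed": network.seed})
    arrays = {k.replace(".", "/"): v for k, v in network.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_checkpoint(path: str | Path) -> Network:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(data["__meta__"].tobytes().decode())
        state = {k.replace("/", "."): data[k] for k in data.files if k != "__meta__"}
    net = Network(ModelConfig(**meta["config"]), seed=meta.get("seed", 0))
    net.load_state_dict(state)
    return net
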