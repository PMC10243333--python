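"""The three residual denoising architectures: DnCNN, Win5RB, ResUnet.

Each model maps a standardized short-time image to a standardized
prediction of the full-time image with identical spatial shape:

* **DnCNN** — Conv3x3+ReLU, then 15 Conv3x3+BN+ReLU units, then a final
  Conv3x3; the network predicts the residual (noise) component and the
  output is ``input - residual`` (17 convolutions; the residual sign is
  configurable).
* **Win5RB** — four Conv7x7+BN+ReLU layers followed by Conv7x7+BN, with an
  additive skip from input to output (5 convolutions; 31x31 receptive
  field).
* **ResUnet** — encoder / bridge / decoder built from pre-activation
  residual units (BN-ReLU-Conv twice plus an identity or 1x1-projection
  shortcut), stride-2 convolution for down-sampling, nearest-neighbour
  upsampling + convolution for up-sampling, encoder-to-decoder channel
  concatenation, and a final 1x1 convolution to one channel.

Checkpoints are a compressed ``.npz`` of the weight arrays next to a JSON
architecture manifest, so a saved model is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, NearestUpsample2x, ReLU, Residual, Sequential

__all__ = ["ArchitectureSpec", "build_dncnn", "build_win5rb", "build_resunet", "build_model",
           "count_convolutions", "save_model", "load_model"]

ARCH_NAMES = ("DnCNN", "Win5RB", "ResUnet")


@dataclass
class ArchitectureSpec:
    """Hyperparameters of one architecture; defaults are the reference setups."""

    name: str = "DnCNN"
    n_filters: int = 64
    dncnn_units: int = 15
    dncnn_residual_sign: int = -1  # output = input + sign * predicted residual
    win5rb_kernel: int = 7
    resunet_level_filters: tuple[int, ...] = (64, 128, 256)
    resunet_bridge_filters: int = 512
    input_channels: int = 1

    def __post_init__(self) -> None:
        canonical = {n.lower(): n for n in ARCH_NAMES}
        key = self.name.lower()
        if key not in canonical:
            raise ValueError(f"unknown architecture {self.name!r}; expected one of {ARCH_NAMES}")
        self.name = canonical[key]
        if self.dncnn_residual_sign not in (-1, 1):
            raise ValueError("dncnn_residual_sign must be -1 or +1")


def build_dncnn(spec: ArchitectureSpec, seed: int = 0) -> Module:
    """[Conv3x3+ReLU] + units x [Conv3x3+BN+ReLU] + [Conv3x3], residual output."""
    rng = np.random.default_rng(seed)
    f, cin = spec.n_filters, spec.input_channels
    layers: list[Module] = [Conv2d(cin, f, 3, rng=rng), ReLU()]
    for _ in range(spec.dncnn_units):
        layers += [Conv2d(f, f, 3, rng=rng), BatchNorm2d(f), ReLU()]
    layers.append(Conv2d(f, cin, 3, rng=rng))
    return Residual(Sequential(layers), sign=spec.dncnn_residual_sign)


def build_win5rb(spec: ArchitectureSpec, seed: int = 0) -> Module:
    """4 x [Conv7x7+BN+ReLU] + [Conv7x7+BN], with input->output skip."""
    rng = np.random.default_rng(seed)
    f, k, cin = spec.n_filters, spec.win5rb_kernel, spec.input_channels
    layers: list[Module] = []
    c = cin
    for _ in range(4):
        layers += [Conv2d(c, f, k, rng=rng), BatchNorm2d(f), ReLU()]
        c = f
    layers += [Conv2d(f, cin, k, rng=rng), BatchNorm2d(cin)]
    return Residual(Sequential(layers), sign=1)


class _ResidualUnit(Module):
    """Pre-activation residual unit: (BN-ReLU-Conv3x3) x 2 + shortcut.

    The first convolution carries the stride; a 1x1 projection shortcut is
    used whenever channels change or the stride is 2.
    """

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.body = Sequential([
            BatchNorm2d(cin), ReLU(), Conv2d(cin, cout, 3, stride=stride, rng=rng),
            BatchNorm2d(cout), ReLU(), Conv2d(cout, cout, 3, rng=rng),
        ])
        self.shortcut = None
        if stride != 1 or cin != cout:
            self.shortcut = Conv2d(cin, cout, 1, stride=stride, rng=rng)

    def children(self):
        out = [("body", self.body)]
        if self.shortcut is not None:
            out.append(("shortcut", self.shortcut))
        return out

    def forward(self, x):
        skip = x if self.shortcut is None else self.shortcut.forward(x)
        return skip + self.body.forward(x)

    def backward(self, gy):
        gx = self.body.backward(gy)
        return gx + (gy if self.shortcut is None else self.shortcut.backward(gy))


class _ResUnet(Module):
    """Encoder - bridge - decoder with concatenation skips."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        filt = list(spec.resunet_level_filters)
        cin = spec.input_channels
        self.levels = len(filt)
        self.enc: list[_ResidualUnit] = []
        c = cin
        for i, f in enumerate(filt):
            self.enc.append(_ResidualUnit(c, f, stride=1 if i == 0 else 2, rng=rng))
            c = f
        self.bridge = _ResidualUnit(c, spec.resunet_bridge_filters, stride=2, rng=rng)
        c = spec.resunet_bridge_filters
        self.up: list[NearestUpsample2x] = []
        self.up_conv: list[Conv2d] = []
        self.dec: list[_ResidualUnit] = []
        for f in reversed(filt):
            self.up.append(NearestUpsample2x())
            self.up_conv.append(Conv2d(c, f, 3, rng=rng))
            self.dec.append(_ResidualUnit(2 * f, f, stride=1, rng=rng))
            c = f
        self.head = Conv2d(c, cin, 1, rng=rng)

    def children(self):
        out = [(f"enc{i}", u) for i, u in enumerate(self.enc)]
        out.append(("bridge", self.bridge))
        for i in range(self.levels):
            out += [(f"up_conv{i}", self.up_conv[i]), (f"dec{i}", self.dec[i])]
        out.append(("head", self.head))
        return out

    def forward(self, x):
        div = 2 ** self.levels
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"ResUnet with {self.levels} levels needs input sides divisible by {div}, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        feats = []
        h = x
        for u in self.enc:
            h = u.forward(h)
            feats.append(h)
        h = self.bridge.forward(h)
        self._split = []
        for i in range(self.levels):
            skip = feats[self.levels - 1 - i]
            h = self.up_conv[i].forward(self.up[i].forward(h))
            self._split.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = self.dec[i].forward(h)
        return self.head.forward(h)

    def backward(self, gy):
        g = self.head.backward(gy)
        gskips = [None] * self.levels
        for i in reversed(range(self.levels)):
            g = self.dec[i].backward(g)
            c = self._split[i]
            g_main, g_skip = g[:, :c], g[:, c:]
            gskips[self.levels - 1 - i] = g_skip
            g = self.up[i].backward(self.up_conv[i].backward(g_main))
        g = self.bridge.backward(g)
        for i in reversed(range(self.levels)):
            g = g + gskips[i]
            g = self.enc[i].backward(g)
        return g


def build_resunet(spec: ArchitectureSpec, seed: int = 0) -> Module:
    return _ResUnet(spec, np.random.default_rng(seed))


_BUILDERS = {"DnCNN": build_dncnn, "Win5RB": build_win5rb, "ResUnet": build_resunet}


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Module:
    return _BUILDERS[spec.name](spec, seed)


def count_convolutions(model: Module) -> int:
    """Number of convolution layers anywhere in a model graph."""
    n = 1 if isinstance(model, Conv2d) else 0
    for _, child in model.children():
        n += count_convolutions(child)
    return n


def save_model(model: Module, spec: ArchitectureSpec, path: str | Path) -> Path:
    """Write weights as ``<path>.npz`` plus a ``<path>.json`` manifest."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    np.savez_compressed(base.with_suffix(".npz"), **model.state_dict())
    base.with_suffix(".json").write_text(json.dumps({"architecture": asdict(spec)}, indent=1))
    return base.with_suffix(".npz")


def load_model(path: str | Path) -> tuple[Module, ArchitectureSpec]:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    manifest = json.loads(base.with_suffix(".json").read_text())
    arch = manifest["architecture"]
    arch["resunet_level_filters"] = tuple(arch["resunet_level_filters"])
    spec = ArchitectureSpec(**arch)
    model = build_model(spec)
    with np.load(base.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, spec
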