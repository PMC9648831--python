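"""The seven CNN classifiers.

All operate on band-power layout images and end in a 2-way softmax head:

* ``stacked_merged`` -- five stride-1 conv layers (10 filters; kernels
  2,2,3,3,3; 'same'; ELU each) on the 10x10 merged image, dropout, dense(2).
* ``single_alpha`` / ``single_beta`` / ``single_low_gamma`` /
  ``single_high_gamma`` -- three conv layers (10 filters; 2,2,3) on one 5x5
  band frame, dropout, dense(2).
* ``parallel_bands`` -- four weight-independent 3-conv branches, one per
  band frame, channel-concatenated (40 x 5 x 5), dropout, dense(2).
* ``inception_merged`` -- three inception modules on the 10x10 image.  Each
  module has four 10-filter branches: 1x1 -> 2x2, 1x1 -> 3x3, 1x1 -> 5x5,
  and maxpool(3x3, stride 1) -> 1x1; the branches concatenate to 40
  channels at 10x10 (so modules 2-3 consume 40x10x10), followed by one ELU.
  Dropout and dense(2) close the network.

'same' padding keeps every feature map at the input's spatial size, so no
spatial information is discarded before the dense head.  Weights are
Glorot-uniform, biases zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigurationError
from .features import BAND_NAMES

ARCHITECTURES: tuple[str, ...] = (
    "inception_merged",
    "stacked_merged",
    "parallel_bands",
    "single_alpha",
    "single_beta",
    "single_low_gamma",
    "single_high_gamma",
)

#: Input tensor shape (C, H, W) per architecture.
INPUT_SHAPES: dict[str, tuple[int, int, int]] = {
    "inception_merged": (1, 10, 10),
    "stacked_merged": (1, 10, 10),
    "parallel_bands": (4, 5, 5),
    **{f"single_{b}": (1, 5, 5) for b in BAND_NAMES},
}

N_FILTERS = 10


@dataclass(frozen=True)
class ModelConfig:
    architecture: str
    n_classes: int = 2
    dropout_rate: float = 0.5
    elu_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture {self.architecture!r}; "
                f"expected one of {ARCHITECTURES}")
        if self.n_classes != 2:
            raise ConfigurationError("n_classes must be 2 (positive/negative)")

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return INPUT_SHAPES[self.architecture]

    @property
    def band(self) -> str | None:
        """Band consumed by a single-band model, else None."""
        if self.architecture.startswith("single_"):
            return self.architecture[len("single_"):]
        return None


def _conv_stack(kernels: list[int], in_channels: int, alpha: float,
                rng: np.random.Generator, is_input: bool = False) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    c = in_channels
    for idx, k in enumerate(kernels):
        layers.append(nn.Conv2D(c, N_FILTERS, k, rng,
                                input_grad=not (is_input and idx == 0)))
        layers.append(nn.ELU(alpha))
        c = N_FILTERS
    return layers


def _inception_module(in_channels: int, alpha: float,
                      rng: np.random.Generator) -> nn.Layer:
    branches = [
        nn.Sequential([nn.Conv2D(in_channels, N_FILTERS, 1, rng),
                       nn.Conv2D(N_FILTERS, N_FILTERS, 2, rng)]),
        nn.Sequential([nn.Conv2D(in_channels, N_FILTERS, 1, rng),
                       nn.Conv2D(N_FILTERS, N_FILTERS, 3, rng)]),
        nn.Sequential([nn.Conv2D(in_channels, N_FILTERS, 1, rng),
                       nn.Conv2D(N_FILTERS, N_FILTERS, 5, rng)]),
        nn.Sequential([nn.MaxPool2D(3),
                       nn.Conv2D(in_channels, N_FILTERS, 1, rng)]),
    ]
    return nn.Sequential([nn.BranchConcat(branches), nn.ELU(alpha)])


def build_model(config: ModelConfig, seed: int = 0) -> nn.Network:
    """Construct a freshly initialised network for ``config``.

    Deterministic in ``seed``: one stream initialises the weights, a second
    independent stream drives dropout.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    init_rng = np.random.Generator(np.random.PCG64(ss))
    drop_rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=seed, spawn_key=(1,))))

    arch = config.architecture
    cin, h, w = config.input_shape
    a = config.elu_alpha
    layers: list[nn.Layer]

    if arch == "stacked_merged":
        layers = _conv_stack([2, 2, 3, 3, 3], cin, a, init_rng, is_input=True)
        feat = N_FILTERS * h * w
    elif arch.startswith("single_"):
        layers = _conv_stack([2, 2, 3], cin, a, init_rng, is_input=True)
        feat = N_FILTERS * h * w
    elif arch == "parallel_bands":
        branches = [nn.Sequential(_conv_stack([2, 2, 3], 1, a, init_rng,
                                              is_input=True))
                    for _ in range(cin)]
        layers = [nn.SplitBranches(branches)]
        feat = cin * N_FILTERS * h * w
    elif arch == "inception_merged":
        layers = [_inception_module(cin, a, init_rng)]
        for _ in range(2):
            layers.append(_inception_module(4 * N_FILTERS, a, init_rng))
        feat = 4 * N_FILTERS * h * w
    else:  # pragma: no cover - guarded by ModelConfig
        raise ConfigurationError(arch)

    layers += [
        nn.Dropout(config.dropout_rate, drop_rng),
        nn.Flatten(),
        nn.Dense(feat, config.n_classes, init_rng),
    ]
    net = nn.Network(nn.Sequential(layers), name=arch)
    net.config = config
    net.input_shape = config.input_shape
    return net


@dataclass
class NetworkSummary:
    """Per-layer table: operator, kernel, output shape, parameter count."""

    name: str
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def n_params(self) -> int:
        return int(sum(r["n_params"] for r in self.rows))

    def count(self, operator: str) -> int:
        return sum(1 for r in self.rows if r["operator"] == operator)


def _chw(shape: tuple[int, ...]) -> tuple[int, ...]:
    """Report an internal (H, W, C) activation shape as (C, H, W)."""
    if len(shape) == 3:
        return (shape[2], shape[0], shape[1])
    return shape


def _walk(layer: nn.Layer, x: np.ndarray, rows: list[dict], prefix: str) -> np.ndarray:
    kind = type(layer).__name__
    if isinstance(layer, nn.Sequential):
        for l in layer.layers:
            x = _walk(l, x, rows, prefix)
        return x
    if isinstance(layer, (nn.BranchConcat, nn.SplitBranches)):
        split = isinstance(layer, nn.SplitBranches)
        outs = []
        for i, b in enumerate(layer.branches):
            xi = np.ascontiguousarray(x[..., i:i + 1]) if split else x
            outs.append(_walk(b, xi, rows, f"{prefix}branch{i}/"))
        out = np.concatenate(outs, axis=-1)
        rows.append({"layer": f"{prefix}concat", "operator": "Concat",
                     "kernel": "-", "output_shape": _chw(out.shape[1:]),
                     "n_params": 0})
        return out
    out = layer.forward(x, train=False)
    kernel = "-"
    if isinstance(layer, nn.Conv2D):
        kernel = f"{layer.out_channels}x{layer.kernel}x{layer.kernel}"
    elif isinstance(layer, nn.MaxPool2D):
        kernel = f"{layer.kernel}x{layer.kernel}"
    n_params = int(sum(w.size for w, _ in layer.params()))
    rows.append({"layer": prefix + kind, "operator": kind, "kernel": kernel,
                 "output_shape": _chw(out.shape[1:]), "n_params": n_params})
    return out


def summarize(network: nn.Network) -> NetworkSummary:
    """Deterministic layer table obtained by a dry run on a zero batch."""
    c, h, w = network.input_shape
    x = np.zeros((1, h, w, c), dtype=nn.DTYPE)
    summary = NetworkSummary(name=network.name)
    _walk(network.body, x, summary.rows, "")
    return summary
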