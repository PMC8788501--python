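"""Multi-scale convolution: Res2Net modules and their cascade.

A Res2Net module passes its input through a 1x1 convolution, splits the
result into S equal channel subsets X_1..X_S and processes them with a
hierarchical chain of 3x3 convolutions:

    Y_1 = X_1
    Y_2 = f_2(X_2)
    Y_i = f_i(X_i + Y_{i-1})      for 2 < i <= S

so the i-th output mixes receptive fields of every subset before it.  The
concatenated Y_1..Y_S are fused by a trailing 1x1 convolution.  The
multi-scale block cascades one 3x3 convolution (which changes the channel
count) with two independent Res2Net modules (which preserve it).

The split count S follows a fixed layer schedule: 4 for the first three
encoder levels and the last two decoder levels, 6 for the two deepest
encoder levels and the first two decoder levels.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .errors import ConfigurationError
from .nn import Tensor, concat

__all__ = [
    "Res2NetConfig", "Res2NetModule", "MultiScaleConv",
    "res2net_block", "multiscale_conv", "scale_schedule",
]


@dataclass(frozen=True)
class Res2NetConfig:
    """Configuration of one multi-scale block."""

    scales: int
    channels_in: int
    channels_out: int

    def __post_init__(self):
        if self.scales < 2:
            raise ConfigurationError(f"scales must be >= 2, got {self.scales}")
        if self.channels_in < 1 or self.channels_out < 1:
            raise ConfigurationError("channel counts must be positive")


class _ConvBlock(nn.Module):
    """Convolution optionally followed by batch norm and ReLU."""

    def __init__(self, cin: int, cout: int, kernel: int, norm: bool, act: bool):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel)
        self.norm = nn.BatchNorm2d(cout) if norm else nn.Identity()
        self.act = nn.ReLU() if act else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.norm(self.conv(x)))


class Res2NetModule(nn.Module):
    """Hierarchical residual module preserving the channel count.

    With ``norm=False`` and all convolutions set to identity kernels the
    module reduces to the cumulative-sum structure Y_i = sum(X_2..X_i) for
    i >= 2, which tests exploit as an exact oracle.
    """

    def __init__(self, channels: int, scales: int, norm: bool = True):
        super().__init__()
        self.channels = channels
        self.scales = scales
        # the leading 1x1 conv projects to the nearest multiple of S, so the
        # split is always exact even when the block width is not
        self.inner = -(-channels // scales) * scales
        self.width = self.inner // scales
        self.conv_in = _ConvBlock(channels, self.inner, 1, norm, norm)
        self.subset_convs = nn.ModuleList(
            [_ConvBlock(self.width, self.width, 3, norm, norm) for _ in range(scales - 1)])
        self.conv_out = _ConvBlock(self.inner, channels, 1, norm, norm)

    def hierarchy(self, u: Tensor) -> list[Tensor]:
        """Apply the hierarchical 3x3 chain to the already-projected input."""
        xs = [u.narrow(1, i * self.width, self.width) for i in range(self.scales)]
        ys = [xs[0]]
        prev = None
        for i in range(1, self.scales):
            inp = xs[i] if prev is None else xs[i] + prev
            prev = self.subset_convs[i - 1](inp)
            ys.append(prev)
        return ys

    def forward(self, x: Tensor) -> Tensor:
        u = self.conv_in(x)
        return self.conv_out(concat(self.hierarchy(u), axis=1))


class MultiScaleConv(nn.Module):
    """Cascade of one 3x3 convolution and two independent Res2Net modules."""

    def __init__(self, cfg: Res2NetConfig, norm: bool = True):
        super().__init__()
        self.cfg = cfg
        self.entry = _ConvBlock(cfg.channels_in, cfg.channels_out, 3, norm, norm)
        self.res1 = Res2NetModule(cfg.channels_out, cfg.scales, norm=norm)
        self.res2 = Res2NetModule(cfg.channels_out, cfg.scales, norm=norm)

    def forward(self, x: Tensor) -> Tensor:
        return self.res2(self.res1(self.entry(x)))


def scale_schedule(stage: str, layer_index: int) -> int:
    """Split count S for one encoder/decoder level (1-based indices).

    Encoder levels 1-3 use S=4 and the two deepest levels S=6; the decoder
    mirrors this: its first two (deepest) levels use 6 and the last two 4.
    """
    if stage == "encoder":
        if not 1 <= layer_index <= 5:
            raise ConfigurationError(f"encoder layer index out of range: {layer_index}")
        return 4 if layer_index <= 3 else 6
    if stage == "decoder":
        if not 1 <= layer_index <= 4:
            raise ConfigurationError(f"decoder layer index out of range: {layer_index}")
        return 6 if layer_index <= 2 else 4
    raise ConfigurationError(f"unknown stage {stage!r}")


# -- functional wrappers on single feature maps -----------------------------

import numpy as np  # noqa: E402


def _run_single(module: nn.Module, x: np.ndarray) -> np.ndarray:
    module.eval()
    with nn.no_grad():
        return module(Tensor(np.asarray(x, dtype=np.float64)[None])).data[0]


def res2net_block(x: np.ndarray, cfg: Res2NetConfig, seed: int = 0,
                  norm: bool = False) -> np.ndarray:
    """Run one freshly initialized Res2Net module on a C×H×W map.

    The standalone block requires an exact split (channels divisible by S);
    inside the network the leading 1x1 conv absorbs any remainder.
    """
    if cfg.channels_out % cfg.scales:
        raise ConfigurationError(
            f"channels ({cfg.channels_out}) not divisible by scales ({cfg.scales})")
    nn.seed_init(seed)
    return _run_single(Res2NetModule(cfg.channels_out, cfg.scales, norm=norm), x)


def multiscale_conv(x: np.ndarray, cfg: Res2NetConfig, seed: int = 0,
                    norm: bool = False) -> np.ndarray:
    """Run one freshly initialized multi-scale block on a C×H×W map."""
    nn.seed_init(seed)
    return _run_single(MultiScaleConv(cfg, norm=norm), x)
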