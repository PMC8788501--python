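"""Channel, position and dual attention gates.

The channel attention module (CAM) summarizes each channel by its spatial
mean and maximum, passes the length-2C descriptor through a two-layer
bottleneck (width C/4) with a sigmoid output, and rescales every channel by
its gate value.  The position attention module (PAM) summarizes every pixel
by the channel-wise maximum, channel-wise mean and a learned 1x1 projection,
turns the three planes into a single gate map with a 3x3 convolution and a
sigmoid, and rescales every pixel.  The dual attention module (DAM) fuses
the two branches by element-wise sum, so with all gate weights at zero each
branch passes 0.5*X and the module is exactly the identity.

Both a functional interface on numpy arrays (single C×H×W feature maps) and
:class:`~vertebox.nn.Module` layers for use inside the network are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidInputError
from .nn import Tensor, concat

__all__ = [
    "GateParams", "channel_descriptor", "position_descriptor",
    "channel_attention", "position_attention", "dual_attention",
    "ChannelAttention", "PositionAttention", "DualAttention",
]


def _validate_feature_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 3:
        raise InvalidInputError(f"feature map must be C×H×W, got shape {x.shape}")
    c, h, w = x.shape
    if c < 1 or h < 1 or w < 1:
        raise InvalidInputError(f"feature map has empty extent: {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("feature map contains non-finite values")
    return x


@dataclass
class GateParams:
    """Learnable parameters of one dual-attention module for C channels.

    CAM bottleneck: ``w1`` (C/4, 2C), ``w2`` (C, C/4) with biases; PAM:
    ``conv1x1`` (1, C, 1, 1) projecting channels to one plane and ``conv3x3``
    (1, 3, 3, 3) collapsing the three descriptor planes to the gate map.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    conv1x1_w: np.ndarray
    conv1x1_b: np.ndarray
    conv3x3_w: np.ndarray
    conv3x3_b: np.ndarray

    def __post_init__(self):
        c = self.w2.shape[0]
        if c % 4:
            raise ConfigurationError(f"channel count {c} not divisible by 4")
        expected = {
            "w1": (c // 4, 2 * c), "b1": (c // 4,), "w2": (c, c // 4), "b2": (c,),
            "conv1x1_w": (1, c, 1, 1), "conv1x1_b": (1,),
            "conv3x3_w": (1, 3, 3, 3), "conv3x3_b": (1,),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape:
                raise ConfigurationError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)

    @property
    def channels(self) -> int:
        return self.w2.shape[0]

    @classmethod
    def zeros(cls, channels: int) -> "GateParams":
        """All-zero gates: every sigmoid evaluates to 0.5 (neutral module)."""
        c = channels
        if c % 4:
            raise ConfigurationError(f"channel count {c} not divisible by 4")
        return cls(
            w1=np.zeros((c // 4, 2 * c)), b1=np.zeros(c // 4),
            w2=np.zeros((c, c // 4)), b2=np.zeros(c),
            conv1x1_w=np.zeros((1, c, 1, 1)), conv1x1_b=np.zeros(1),
            conv3x3_w=np.zeros((1, 3, 3, 3)), conv3x3_b=np.zeros(1),
        )

    @classmethod
    def random(cls, channels: int, seed: int = 0) -> "GateParams":
        rng = np.random.default_rng(seed)
        p = cls.zeros(channels)
        for name in ("w1", "w2", "conv1x1_w", "conv3x3_w"):
            arr = getattr(p, name)
            fan_in = arr.size // arr.shape[0]
            bound = np.sqrt(6.0 / fan_in)
            setattr(p, name, rng.uniform(-bound, bound, size=arr.shape))
        return p


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def channel_descriptor(x: np.ndarray) -> np.ndarray:
    """Length-2C channel descriptor: per-channel spatial means then maxima."""
    x = _validate_feature_map(x)
    return np.concatenate([x.mean(axis=(1, 2)), x.max(axis=(1, 2))])


def position_descriptor(x: np.ndarray, params: GateParams,
                        literal_sum: bool = False) -> np.ndarray:
    """3×H×W position descriptor: channel max, channel mean (or sum), 1x1 proj."""
    x = _validate_feature_map(x)
    pooled = x.sum(axis=0) if literal_sum else x.mean(axis=0)
    proj = np.einsum("chw,c->hw", x, params.conv1x1_w[0, :, 0, 0]) + params.conv1x1_b[0]
    return np.stack([x.max(axis=0), pooled, proj])


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class ChannelAttention(nn.Module):
    """Squeeze-style channel gate: avg+max descriptor -> bottleneck -> sigmoid."""

    def __init__(self, channels: int):
        super().__init__()
        if channels % 4:
            raise ConfigurationError(f"channel count {channels} not divisible by 4")
        self.channels = channels
        self.fc1 = nn.Linear(2 * channels, channels // 4)
        self.fc2 = nn.Linear(channels // 4, channels)

    def gate(self, x: Tensor) -> Tensor:
        z = concat([x.mean(axis=(2, 3)), x.max(axis=(2, 3))], axis=1)  # (N, 2C)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        s = self.gate(x).reshape(n, c, 1, 1)
        return x * s


class PositionAttention(nn.Module):
    """Pixel gate from channel max/mean planes and a learned 1x1 projection."""

    def __init__(self, channels: int, literal_sum: bool = False):
        super().__init__()
        self.channels = channels
        self.literal_sum = literal_sum
        self.proj = nn.Conv2d(channels, 1, 1)
        self.gate_conv = nn.Conv2d(3, 1, 3)

    def gate(self, x: Tensor) -> Tensor:
        pooled = x.sum(axis=1, keepdims=True) if self.literal_sum \
            else x.mean(axis=1, keepdims=True)
        zp = concat([x.max(axis=1, keepdims=True), pooled, self.proj(x)], axis=1)
        return self.gate_conv(zp).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class DualAttention(nn.Module):
    """Element-wise sum of the channel and position attention branches."""

    def __init__(self, channels: int, literal_sum: bool = False):
        super().__init__()
        self.cam = ChannelAttention(channels)
        self.pam = PositionAttention(channels, literal_sum=literal_sum)

    def forward(self, x: Tensor) -> Tensor:
        return self.cam(x) + self.pam(x)

    def load_gate_params(self, params: GateParams) -> None:
        _load_cam(self.cam, params)
        _load_pam(self.pam, params)


def _load_cam(cam: ChannelAttention, params: GateParams) -> None:
    cam.fc1.weight.data = params.w1.astype(np.float64)
    cam.fc1.bias.data = params.b1.astype(np.float64)
    cam.fc2.weight.data = params.w2.astype(np.float64)
    cam.fc2.bias.data = params.b2.astype(np.float64)


def _load_pam(pam: PositionAttention, params: GateParams) -> None:
    pam.proj.weight.data = params.conv1x1_w.astype(np.float64)
    pam.proj.bias.data = params.conv1x1_b.astype(np.float64)
    pam.gate_conv.weight.data = params.conv3x3_w.astype(np.float64)
    pam.gate_conv.bias.data = params.conv3x3_b.astype(np.float64)


# ---------------------------------------------------------------------------
# functional interface on single feature maps
# ---------------------------------------------------------------------------

def _run_single(module: nn.Module, x: np.ndarray) -> np.ndarray:
    x = _validate_feature_map(x).astype(np.float64)
    with nn.no_grad():
        out = module(Tensor(x[None]))
    return out.data[0]


def channel_attention(x: np.ndarray, params: GateParams) -> np.ndarray:
    """Rescale each channel of ``x`` (C×H×W) by its learned gate in (0,1)."""
    cam = ChannelAttention(params.channels)
    _load_cam(cam, params)
    return _run_single(cam, x)


def position_attention(x: np.ndarray, params: GateParams,
                       literal_sum: bool = False) -> np.ndarray:
    """Rescale each pixel of ``x`` (C×H×W) by its learned gate in (0,1)."""
    pam = PositionAttention(params.channels, literal_sum=literal_sum)
    _load_pam(pam, params)
    return _run_single(pam, x)


def dual_attention(x: np.ndarray, params: GateParams,
                   literal_sum: bool = False) -> np.ndarray:
    """Sum of the channel- and position-attention branch outputs."""
    out = channel_attention(x, params) + position_attention(x, params, literal_sum)
    if out.shape != np.asarray(x).shape:
        raise AssertionError("attention branches changed the feature map shape")
    return out
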