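"""The Verte-Box encoder–decoder segmentation network.

Three stages:

* **feature extraction** — five multi-scale convolution levels; each level
  after the first is preceded by 2x2 max pooling, doubling the channel count
  and halving the spatial size (ladder 256, 128, 64, 32, 16 at input 256);
* **central processing** — channel attention on each of the four skip
  features, dual (channel + position) attention on the deepest feature;
* **prediction ("feature box")** — four decoder levels, each upsampling with
  a learned 2x2 transposed convolution, concatenating the attended skip and
  applying a multi-scale block.  Every decoder feature yields a coarse
  class-score map through a 1x1 head, bilinearly upsampled to the input
  resolution; the four coarse maps are concatenated and fused by a final 1x1
  convolution into the fine prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import ChannelAttention, DualAttention
from .errors import ConfigurationError, InvalidInputError
from .msconv import MultiScaleConv, Res2NetConfig, scale_schedule
from .nn import Tensor, concat

__all__ = [
    "NetworkConfig", "PredictionSet", "VerteBox", "build_vertebox",
    "predict_labels", "save_checkpoint", "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Structural configuration of the network."""

    in_channels: int = 1
    num_classes: int = 2
    base_width: int = 64
    input_size: int = 256
    attention: bool = True
    norm: bool = True

    def __post_init__(self):
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if self.base_width % 4:
            raise ConfigurationError("base_width must be divisible by 4 (attention bottleneck)")
        if self.input_size % 32:
            raise ConfigurationError("input_size must be divisible by 2^5")
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be positive")

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2 ** i for i in range(5))


@dataclass
class PredictionSet:
    """Four auxiliary coarse score maps plus the final fused map.

    ``aux[0]`` comes from the deepest decoder level and ``aux[3]`` from the
    full-resolution one; all five maps are (N, num_classes, H, W) at input
    resolution.
    """

    aux: list
    final: object

    def __post_init__(self):
        if len(self.aux) != 4:
            raise InvalidInputError(f"expected 4 auxiliary maps, got {len(self.aux)}")

    def maps(self) -> list:
        return list(self.aux) + [self.final]

    def numpy(self) -> "PredictionSet":
        def _np(t):
            return t.data if isinstance(t, Tensor) else np.asarray(t)
        return PredictionSet([_np(t) for t in self.aux], _np(self.final))


class VerteBox(nn.Module):
    """Encoder–decoder with dual attention and deeply supervised feature box."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        w = cfg.encoder_widths  # e.g. (64, 128, 256, 512, 1024)

        self.encoder = nn.ModuleList([
            MultiScaleConv(Res2NetConfig(
                scales=scale_schedule("encoder", i + 1),
                channels_in=cfg.in_channels if i == 0 else w[i - 1],
                channels_out=w[i]), norm=cfg.norm)
            for i in range(5)
        ])
        if cfg.attention:
            self.skip_attn = nn.ModuleList([ChannelAttention(w[i]) for i in range(4)])
            self.bottleneck_attn = DualAttention(w[4])
        else:
            self.skip_attn = nn.ModuleList([nn.Identity() for _ in range(4)])
            self.bottleneck_attn = nn.Identity()

        # decoder level j consumes w[5-j] channels and produces w[4-j]
        self.up = nn.ModuleList([nn.ConvTranspose2d(w[4 - j], w[3 - j], 2)
                                 for j in range(4)])
        self.decoder = nn.ModuleList([
            MultiScaleConv(Res2NetConfig(
                scales=scale_schedule("decoder", j + 1),
                channels_in=2 * w[3 - j],
                channels_out=w[3 - j]), norm=cfg.norm)
            for j in range(4)
        ])
        self.heads = nn.ModuleList([nn.Conv2d(w[3 - j], cfg.num_classes, 1)
                                    for j in range(4)])
        self.fuse = nn.Conv2d(4 * cfg.num_classes, cfg.num_classes, 1)

    def encoder_features(self, x) -> tuple[list, object]:
        """Run the feature-extraction and central-processing stages.

        Returns ``(attended_skips, attended_bottleneck)``; the four skip
        features carry channel attention and the deepest feature dual
        attention.
        """
        x = nn.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise InvalidInputError(
                f"expected (N,{self.cfg.in_channels},H,W) input, got shape {x.shape}")
        size = self.cfg.input_size
        if x.shape[2] != size or x.shape[3] != size:
            raise InvalidInputError(
                f"input spatial size {x.shape[2:]} does not match configured {size}")
        skips = []
        feat = x
        for i, block in enumerate(self.encoder):
            if i > 0:
                feat = nn.max_pool2d(feat, 2)
            feat = block(feat)
            if i < 4:
                skips.append(self.skip_attn[i](feat))
        return skips, self.bottleneck_attn(feat)

    def forward(self, x) -> PredictionSet:
        skips, feat = self.encoder_features(x)
        size = self.cfg.input_size

        aux = []
        for j in range(4):
            feat = self.up[j](feat)
            feat = self.decoder[j](concat([skips[3 - j], feat], axis=1))
            coarse = self.heads[j](feat)
            if coarse.shape[2] != size:
                coarse = nn.upsample_bilinear(coarse, (size, size))
            aux.append(coarse)

        final = self.fuse(concat(aux, axis=1))
        return PredictionSet(aux, final)


def build_vertebox(cfg: NetworkConfig, seed: int | None = None) -> VerteBox:
    """Build a (reproducibly initialized, if seeded) Verte-Box model."""
    if seed is not None:
        nn.seed_init(seed)
    return VerteBox(cfg)


def predict_labels(pred) -> np.ndarray:
    """Per-pixel argmax of the FINAL map only; ties go to the lower class.

    Accepts a :class:`PredictionSet`, a tensor or an array of class scores
    with the class axis second ((N, C, H, W)) or first ((C, H, W)).
    """
    if isinstance(pred, PredictionSet):
        scores = pred.final
    else:
        scores = pred
    if isinstance(scores, Tensor):
        scores = scores.data
    scores = np.asarray(scores)
    axis = 1 if scores.ndim == 4 else 0
    return scores.argmax(axis=axis)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: VerteBox, path, extra: dict | None = None) -> None:
    """Single-file .npz checkpoint: version tag, config, weights, extras."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": vars(model.cfg) if not hasattr(model.cfg, "__dataclass_fields__")
                  else {k: getattr(model.cfg, k) for k in model.cfg.__dataclass_fields__},
        "extra": extra or {},
    }
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[VerteBox, dict]:
    """Rebuild a model from a checkpoint; returns (model, extra metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise InvalidInputError(f"unsupported checkpoint version {meta.get('version')}")
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model = VerteBox(NetworkConfig(**meta["config"]))
    model.load_state_dict(state)
    model.eval()
    return model, meta["extra"]
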