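"""YAML run configuration: network / data / loss / train sections."""

from __future__ import annotations

from pathlib import Path

import yaml

from .losses import LossWeights
from .network import NetworkConfig
from .trainer import TrainConfig

__all__ = ["RunConfig", "load_config"]


class RunConfig:
    """Parsed run configuration with typed sections."""

    def __init__(self, network: NetworkConfig, train: TrainConfig,
                 loss: LossWeights, data: dict):
        self.network = network
        self.train = train
        self.loss = loss
        self.data = data

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        net = raw.get("network", {})
        loss = dict(raw.get("loss", {}))
        loss.pop("epsilon", None)  # epsilon is passed to the loss call, not stored
        if "lambda_aux" in loss:
            loss["lambda_aux"] = tuple(loss["lambda_aux"])
        return cls(
            network=NetworkConfig(**net),
            train=TrainConfig(**raw.get("train", {})),
            loss=LossWeights(**loss),
            data=dict(raw.get("data", {})),
        )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(raw)
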