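import numpy as np
import pytest

from vertebox import NetworkConfig, TrainConfig, generate_dataset, train
from vertebox.data_io import resize_pair
from vertebox.network import save_checkpoint

OVERFIT_SEED = 0
PHANTOM_SEED = 7


@pytest.fixture(scope="session")
def phantom_pairs_64():
    """Eight mixed-profile phantoms resized to the miniature input size."""
    pairs, _ = generate_dataset(8, profile="mixed", seed=PHANTOM_SEED)
    return [resize_pair(p, 64) for p in pairs]


@pytest.fixture(scope="session")
def overfit_run(phantom_pairs_64, tmp_path_factory):
    """Miniature network overfit on 8 phantoms (<= 300 optimizer steps).

    Shared session-wide: the capacity check, prediction tests and volume
    inference tests all reuse this single training run.
    """
    net = NetworkConfig(base_width=8, input_size=64)
    cfg = TrainConfig(batch_size=8, max_epochs=300, max_steps=300, seed=OVERFIT_SEED)
    model, state = train(net, (phantom_pairs_64, []), cfg)
    ckpt = tmp_path_factory.mktemp("overfit") / "model.npz"
    save_checkpoint(model, ckpt)
    return model, state, ckpt
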