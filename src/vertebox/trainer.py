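"""Training loop, plateau learning-rate schedule and volume inference.

Training uses AdamW (lr 0.001, mini-batch 16, weight decay 0.01 by default)
with the deeply supervised Dice loss; after every epoch the validation Dice
of the final head's hard predictions is computed (slice-averaged), and when
it fails to improve on the best value for ``plateau_patience`` consecutive
epochs the learning rate is multiplied by ``lr_factor`` (halved).  The best
model by validation Dice is checkpointed; the per-epoch history and the full
optimizer/RNG state are saved so interrupted runs resume exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data_io import SlicePair, augment as augment_pair, normalize_intensity, \
    resample_isotropic, slice_and_resize
from .errors import ConfigurationError, InvalidInputError
from .losses import LossWeights, deep_supervision_loss, one_hot
from .metrics import dsc
from .network import NetworkConfig, VerteBox, build_vertebox, load_checkpoint, \
    predict_labels, save_checkpoint

__all__ = [
    "TrainConfig", "TrainState", "lr_step", "train", "dataset_dsc",
    "predict_volume",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults follow the training protocol."""

    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    plateau_patience: int = 10
    lr_factor: float = 0.5
    weight_decay: float = 0.01
    seed: int = 0
    min_lr: float | None = None
    max_steps: int | None = None
    augment: bool = False

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")
        if not 0 < self.lr_factor < 1:
            raise ConfigurationError("lr_factor must be in (0,1)")
        if self.plateau_patience < 1:
            raise ConfigurationError("plateau_patience must be >= 1")


@dataclass
class TrainState:
    """Progress of one training run (a pure value for the schedule machine)."""

    epoch: int = 0
    best_val_dsc: float = -np.inf
    epochs_since_improve: int = 0
    current_lr: float = 1e-3
    history: list = field(default_factory=list)


def lr_step(state: TrainState, val_dsc: float, patience: int = 10,
            factor: float = 0.5, min_lr: float | None = None) -> TrainState:
    """Plateau schedule step: strict improvement resets the counter; after
    ``patience`` consecutive non-improving epochs the rate is scaled by
    ``factor`` and the counter resets.  Returns a new state."""
    state = dataclasses.replace(state, history=list(state.history))
    if val_dsc > state.best_val_dsc:
        state.best_val_dsc = float(val_dsc)
        state.epochs_since_improve = 0
    else:
        state.epochs_since_improve += 1
        if state.epochs_since_improve >= patience:
            new_lr = state.current_lr * factor
            if min_lr is not None:
                new_lr = max(new_lr, min_lr)
            state.current_lr = new_lr
            state.epochs_since_improve = 0
    return state


def _make_batch(pairs: list[SlicePair], idxs, num_classes: int):
    images = np.stack([pairs[i].image for i in idxs])[:, None].astype(np.float32)
    masks = np.stack([pairs[i].mask for i in idxs])
    return images, one_hot(masks, num_classes), masks


def dataset_dsc(model: VerteBox, pairs: list[SlicePair], batch_size: int = 8) -> float:
    """Slice-averaged Dice of the final head's hard predictions."""
    model.eval()
    scores = []
    with nn.no_grad():
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start:start + batch_size]
            images = np.stack([p.image for p in chunk])[:, None].astype(np.float32)
            labels = predict_labels(model(images))
            for p, lab in zip(chunk, labels):
                scores.append(dsc((lab == 1).astype(np.uint8), p.mask))
    model.train()
    return float(np.mean(scores))


def train(net_cfg: NetworkConfig, data, cfg: TrainConfig,
          loss_weights: LossWeights | None = None, out_dir=None,
          resume_from=None, on_step=None, verbose: bool = False):
    """Train a Verte-Box on (train_pairs, val_pairs) slice lists.

    Returns ``(model, state)`` where ``state.history`` holds one dict per
    epoch with train_loss, val_dsc and lr.  ``on_step(step, batch_pairs,
    preds, loss)`` is invoked after every optimizer step (testing hook).  With ``out_dir``
    the best-by-validation-Dice model and the training state are saved there.
    """
    train_pairs, val_pairs = data
    if not train_pairs:
        raise InvalidInputError("empty training dataset")
    loss_weights = loss_weights or LossWeights()

    if resume_from is not None:
        model, extra = load_checkpoint(Path(resume_from) / "last.npz")
        model.train()
        opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        with np.load(Path(resume_from) / "optim.npz") as f:
            opt.load_state_dict(dict(f.items()))
        state = TrainState(**{k: extra["state"][k] for k in
                              ("epoch", "best_val_dsc", "epochs_since_improve", "current_lr")},
                           history=extra["state"]["history"])
        rng = np.random.default_rng()
        rng.bit_generator.state = extra["rng_state"]
    else:
        model = build_vertebox(net_cfg, seed=cfg.seed)
        opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        state = TrainState(current_lr=cfg.lr)
        rng = np.random.default_rng(cfg.seed)

    num_classes = net_cfg.num_classes
    step = 0
    stop = False
    best_path = Path(out_dir) / "best.npz" if out_dir else None
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)

    for epoch in range(state.epoch, cfg.max_epochs):
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idxs = order[start:start + cfg.batch_size]
            batch_pairs = [train_pairs[i] for i in idxs]
            if cfg.augment:
                batch_pairs = [augment_pair(p, seed=int(rng.integers(2 ** 31)))
                               for p in batch_pairs]
            images = np.stack([p.image for p in batch_pairs])[:, None].astype(np.float32)
            y = one_hot(np.stack([p.mask for p in batch_pairs]), num_classes)

            preds = model(images)
            loss = deep_supervision_loss(y, preds, loss_weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at step {step}")
            model.zero_grad()
            loss.backward()
            opt.lr = state.current_lr
            opt.step()
            epoch_losses.append(float(loss.data))
            if on_step is not None:
                on_step(step, batch_pairs, preds, float(loss.data))
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                stop = True
                break

        val_dsc = dataset_dsc(model, val_pairs) if val_pairs else \
            dataset_dsc(model, train_pairs)
        improved = val_dsc > state.best_val_dsc
        state = lr_step(state, val_dsc, patience=cfg.plateau_patience,
                        factor=cfg.lr_factor, min_lr=cfg.min_lr)
        state.epoch = epoch + 1
        state.history.append({"epoch": epoch + 1,
                              "train_loss": float(np.mean(epoch_losses)),
                              "val_dsc": float(val_dsc),
                              "lr": state.current_lr})
        if verbose:
            print(f"epoch {epoch + 1}: loss {np.mean(epoch_losses):.4f} "
                  f"val_dsc {val_dsc:.4f} lr {state.current_lr:.2e}")
        if out_dir:
            _save_run(out_dir, model, opt, state, rng)
            if improved:
                save_checkpoint(model, best_path, extra={"val_dsc": val_dsc,
                                                         "epoch": epoch + 1})
        if stop:
            break
    return model, state


def _save_run(out_dir, model, opt, state: TrainState, rng) -> None:
    out = Path(out_dir)
    extra = {"state": dataclasses.asdict(state), "rng_state": rng.bit_generator.state}
    save_checkpoint(model, out / "last.npz", extra=extra)
    np.savez(out / "optim.npz", **opt.state_dict())
    with open(out / "history.csv", "w") as fh:
        fh.write("epoch,train_loss,val_dsc,lr\n")
        for row in state.history:
            fh.write(f"{row['epoch']},{row['train_loss']},{row['val_dsc']},{row['lr']}\n")


# ---------------------------------------------------------------------------
# volume inference
# ---------------------------------------------------------------------------

def predict_volume(checkpoint_path, volume, meta=None, window=None):
    """Segment a CT volume slice by slice with a trained model.

    ``volume`` may be a path (read from disk) or a (z,y,x) array with its
    :class:`VolumeMeta`.  The volume is resampled to 1 mm isotropic spacing,
    intensity-normalized, sliced and resized exactly as in training (without
    augmentation), predicted per slice, and the per-slice label maps are
    resized back (nearest) and restacked onto the input volume grid.
    """
    import SimpleITK as sitk
    from skimage.transform import resize as sk_resize

    from .data_io import HU_WINDOW, VolumeMeta, load_volume

    model, _ = load_checkpoint(checkpoint_path)
    size = model.cfg.input_size

    if meta is None:
        volume, _, meta = load_volume(volume)
    orig_shape = np.asarray(volume).shape
    iso, _, iso_meta = resample_isotropic(np.asarray(volume, np.float32), meta)
    norm = normalize_intensity(iso, window=window or HU_WINDOW)

    labels_iso = np.zeros(norm.shape, dtype=np.uint8)
    batch = 8
    slices = [sk_resize(norm[k], (size, size), order=1, preserve_range=True,
                        anti_aliasing=False).astype(np.float32)
              for k in range(norm.shape[0])]
    model.eval()
    with nn.no_grad():
        for start in range(0, len(slices), batch):
            chunk = np.stack(slices[start:start + batch])[:, None]
            lab = predict_labels(model(chunk))
            for j, l in enumerate(lab):
                back = sk_resize(l.astype(np.uint8), norm.shape[1:], order=0,
                                 preserve_range=True).astype(np.uint8)
                labels_iso[start + j] = back

    if labels_iso.shape == orig_shape:
        return labels_iso
    # restack onto the original grid
    lab_img = sitk.GetImageFromArray(labels_iso)
    lab_img.SetSpacing(iso_meta.spacing)
    lab_img.SetOrigin(iso_meta.origin)
    lab_img.SetDirection(iso_meta.direction)
    ref = sitk.Image(int(orig_shape[2]), int(orig_shape[1]), int(orig_shape[0]), sitk.sitkUInt8)
    ref.SetSpacing(meta.spacing)
    ref.SetOrigin(meta.origin)
    ref.SetDirection(meta.direction)
    out = sitk.Resample(lab_img, ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0)
    return sitk.GetArrayFromImage(out).astype(np.uint8)
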