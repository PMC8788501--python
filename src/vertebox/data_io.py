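"""CT volume I/O and the slice-level preprocessing pipeline.

Volumes (NIfTI ``.nii``/``.nii.gz`` or MetaImage ``.mhd``) are read with
SimpleITK, resampled to 1 mm isotropic spacing (linear interpolation for
intensities, nearest-neighbor for labels), intensity-windowed and scaled to
[0, 1], sliced along the axial plane and resized to a fixed in-plane size.
Arrays are kept in (z, y, x) index order; ``VolumeMeta.spacing`` follows the
ITK (x, y, z) convention.

Training-time augmentation applies, each with probability 0.5: a small
rotation (angle uniform in ±0.1 rad), a horizontal flip, a contrast scaling
and additive Gaussian noise; masks are transformed with nearest-neighbor
interpolation and stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from skimage.transform import resize as sk_resize, rotate as sk_rotate

from .errors import InvalidInputError

__all__ = [
    "VolumeMeta", "SlicePair", "load_volume", "save_volume",
    "resample_isotropic", "normalize_intensity", "slice_and_resize",
    "augment", "split_train_val",
]

HU_WINDOW = (-200.0, 1200.0)  # encloses soft tissue and trabecular/cortical bone


@dataclass
class VolumeMeta:
    """Geometric metadata of a volume; spacing/origin in ITK (x, y, z) order."""

    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    dtype: str = "float32"

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")


@dataclass
class SlicePair:
    """One axial image/mask slice with provenance (volume id, slice index)."""

    image: np.ndarray
    mask: np.ndarray
    volume_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise InvalidInputError("image and mask shapes differ")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise InvalidInputError("mask must be binary")
        self.mask = self.mask.astype(np.uint8)


def _to_sitk(volume: np.ndarray, meta: VolumeMeta) -> sitk.Image:
    img = sitk.GetImageFromArray(volume)
    img.SetSpacing(meta.spacing)
    img.SetOrigin(meta.origin)
    img.SetDirection(meta.direction)
    return img


def _meta_from(img: sitk.Image, dtype: str) -> VolumeMeta:
    return VolumeMeta(spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()),
                      direction=tuple(img.GetDirection()), dtype=dtype)


def load_volume(image_path, label_path=None):
    """Read an intensity volume (and optional label volume) from disk.

    Returns ``(volume, labels, meta)`` with arrays in (z, y, x) order;
    ``labels`` is None when no label path is given.
    """
    image_path = Path(image_path)
    if not image_path.exists():
        raise InvalidInputError(f"no such file: {image_path}")
    try:
        img = sitk.ReadImage(str(image_path))
    except RuntimeError as exc:
        raise InvalidInputError(f"unreadable volume {image_path}: {exc}") from exc
    volume = sitk.GetArrayFromImage(img)
    meta = _meta_from(img, str(volume.dtype))
    labels = None
    if label_path is not None:
        lab_img = sitk.ReadImage(str(label_path))
        labels = sitk.GetArrayFromImage(lab_img)
        if labels.shape != volume.shape:
            raise InvalidInputError(
                f"label shape {labels.shape} does not match image shape {volume.shape}")
    return volume, labels, meta


def save_volume(volume: np.ndarray, meta: VolumeMeta, path) -> None:
    sitk.WriteImage(_to_sitk(np.asarray(volume), meta), str(path))


def resample_isotropic(volume: np.ndarray, meta: VolumeMeta, labels=None,
                       target: float = 1.0):
    """Resample to isotropic ``target`` mm spacing.

    Linear interpolation for the intensity volume, nearest-neighbor for the
    label volume; the output extent is round(extent * spacing / target).
    Already-isotropic input is returned unchanged.
    """
    if target <= 0:
        raise InvalidInputError("target spacing must be positive")
    if np.allclose(meta.spacing, target):
        return (volume, labels, meta) if labels is not None else (volume, None, meta)

    img = _to_sitk(np.asarray(volume, dtype=np.float32), meta)
    new_size = [max(1, int(round(sz * sp / target)))
                for sz, sp in zip(img.GetSize(), img.GetSpacing())]

    def _resample(im, interp):
        return sitk.Resample(im, new_size, sitk.Transform(), interp,
                             im.GetOrigin(), (target, target, target),
                             im.GetDirection(), 0.0, im.GetPixelID())

    out = sitk.GetArrayFromImage(_resample(img, sitk.sitkLinear))
    out_labels = None
    if labels is not None:
        lab = _to_sitk(np.asarray(labels, dtype=np.uint8), meta)
        out_labels = sitk.GetArrayFromImage(_resample(lab, sitk.sitkNearestNeighbor))
    new_meta = VolumeMeta(spacing=(target, target, target), origin=meta.origin,
                          direction=meta.direction, dtype=meta.dtype)
    return out, out_labels, new_meta


def normalize_intensity(volume: np.ndarray, window=HU_WINDOW) -> np.ndarray:
    """Clip intensities to ``window`` and scale that window affinely to [0,1].

    The mapping is fixed by the window bounds (not by the volume content), so
    the same tissue always lands at the same normalized intensity and
    training/inference distributions agree.
    """
    lo, hi = window
    if hi <= lo:
        raise InvalidInputError("window upper bound must exceed lower bound")
    v = np.clip(np.asarray(volume, dtype=np.float32), lo, hi)
    return (v - lo) / (hi - lo)


def slice_and_resize(volume: np.ndarray, labels: np.ndarray, size: int = 256,
                     volume_id: str = "") -> list[SlicePair]:
    """One SlicePair per axial slice, resized to ``size``x``size``.

    Images use linear interpolation; masks use nearest-neighbor (order 0) so
    they stay binary.  Intensities are assumed already normalized to [0,1].
    """
    volume = np.asarray(volume, dtype=np.float32)
    labels = np.asarray(labels)
    if volume.shape != labels.shape:
        raise InvalidInputError("volume and labels shapes differ")
    pairs = []
    for k in range(volume.shape[0]):
        img = sk_resize(volume[k], (size, size), order=1, preserve_range=True,
                        anti_aliasing=False).astype(np.float32)
        msk = sk_resize(labels[k].astype(np.uint8), (size, size), order=0,
                        preserve_range=True, anti_aliasing=False).astype(np.uint8)
        pairs.append(SlicePair(np.clip(img, 0.0, 1.0), msk, volume_id, k))
    return pairs


def resize_pair(pair: SlicePair, size: int) -> SlicePair:
    """Resize one slice pair (linear image, nearest mask) to ``size``x``size``."""
    img = sk_resize(pair.image, (size, size), order=1, preserve_range=True,
                    anti_aliasing=False).astype(np.float32)
    msk = sk_resize(pair.mask, (size, size), order=0,
                    preserve_range=True).astype(np.uint8)
    return SlicePair(np.clip(img, 0.0, 1.0), msk, pair.volume_id, pair.slice_index)


def augment(pair: SlicePair, seed: int, max_angle: float = 0.1,
            contrast_range=(0.8, 1.2), noise_sigma_max: float = 0.02) -> SlicePair:
    """Seeded random augmentation of one slice pair.

    Each transform fires independently with probability 0.5: rotation by an
    angle uniform in ±``max_angle`` radians, horizontal flip, contrast
    scaling about the image mean, additive Gaussian noise (image only).
    The output image is clipped to [0,1]; the mask stays binary.
    """
    rng = np.random.default_rng(seed)
    img = pair.image.copy()
    msk = pair.mask.copy()

    if rng.random() < 0.5:
        angle_deg = float(np.degrees(rng.uniform(-max_angle, max_angle)))
        img = sk_rotate(img, angle_deg, order=1, preserve_range=True).astype(np.float32)
        msk = sk_rotate(msk.astype(float), angle_deg, order=0,
                        preserve_range=True).astype(np.uint8)
    if rng.random() < 0.5:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    if rng.random() < 0.5:
        factor = rng.uniform(*contrast_range)
        mean = img.mean()
        img = mean + factor * (img - mean)
    if rng.random() < 0.5:
        sigma = rng.uniform(0.0, noise_sigma_max)
        img = img + rng.normal(0.0, sigma, size=img.shape).astype(np.float32)

    return SlicePair(np.clip(img, 0.0, 1.0), msk, pair.volume_id, pair.slice_index)


def split_train_val(pairs: list[SlicePair], train_fraction: float = 0.8,
                    seed: int = 0):
    """4:1 train/validation split of slices, stratified by volume id.

    Slices are shuffled within each volume and split so every volume
    contributes ~``train_fraction`` of its slices to the training list; no
    slice appears in both lists.
    """
    if not 0 < train_fraction < 1:
        raise InvalidInputError("train_fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    by_volume: dict[str, list[SlicePair]] = {}
    for p in pairs:
        by_volume.setdefault(p.volume_id, []).append(p)
    train, val = [], []
    for vid in sorted(by_volume):
        group = list(by_volume[vid])
        order = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        for j, idx in enumerate(order):
            (train if j < n_train else val).append(group[idx])
    return train, val
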