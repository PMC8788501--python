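"""Synthetic vertebra phantoms: axial-slice lookalikes with known masks.

Each phantom is a 2D grayscale slice containing one bright vertebra-like
object — an elliptical body plus up to three attached process rectangles
(one spinous pointing posterior, two transverse) — over a darker soft-tissue
background.  Three challenge ingredients mimic what makes real vertebra CT
hard: gray-matched elliptical distractor blobs (soft tissue whose intensity
is close to bone, NOT part of the mask), an optional hyper-intense lesion
patch inside the body (part of the mask), and additive Gaussian noise.
Geometry is deliberately minimal: the value of the phantoms is the exact
ground truth and the controlled difficulty, not anatomical realism.

Everything is a pure function of the :class:`PhantomSpec` (including its
seed), so datasets are bit-reproducible and replayable from their manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import SlicePair, VolumeMeta
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "PhantomSpec", "generate_phantom", "generate_dataset",
    "generate_phantom_volume", "PROFILES",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic vertebra slice.

    ``body_axes`` are the (row, column) semi-axes of the vertebral-body
    ellipse in pixels; ``n_processes`` counts the attached rectangles
    (spinous, then left/right transverse); distractor placement and the
    lesion position are drawn deterministically from ``seed``.
    """

    image_size: int = 256
    body_center: tuple = (140.0, 128.0)
    body_axes: tuple = (30.0, 42.0)
    body_intensity: float = 0.65
    n_processes: int = 3
    process_length: float = 26.0
    process_width: float = 8.0
    n_distractors: int = 0
    distractor_offset: float = 0.03
    lesion: bool = False
    lesion_boost: float = 0.25
    background: float = 0.20
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_processes <= 3:
            raise ConfigurationError("n_processes must be 1..3")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        for value in (self.body_intensity, self.background):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError("intensities must lie in [0,1]")
        for y0, y1, x0, x1 in self.process_rects():
            s = self.image_size
            if y0 < 0 or x0 < 0 or y1 > s or x1 > s:
                raise InvalidInputError("process geometry out of image bounds")
        cy, cx = self.body_center
        ay, ax = self.body_axes
        if cy - ay < 0 or cy + ay > self.image_size or cx - ax < 0 or cx + ax > self.image_size:
            raise InvalidInputError("body ellipse out of image bounds")

    # -- derived geometry ----------------------------------------------------

    def process_rects(self) -> list[tuple[float, float, float, float]]:
        """Axis-aligned (y0, y1, x0, x1) rectangles of the attached processes."""
        cy, cx = self.body_center
        ay, ax = self.body_axes
        L, w = self.process_length, self.process_width
        rects = [
            (cy + 0.8 * ay, cy + 0.8 * ay + L, cx - w / 2, cx + w / 2),   # spinous
            (cy - w / 2, cy + w / 2, cx - 0.8 * ax - L, cx - 0.8 * ax),   # left transverse
            (cy - w / 2, cy + w / 2, cx + 0.8 * ax, cx + 0.8 * ax + L),   # right transverse
        ]
        return rects[: self.n_processes]

    def derived_features(self):
        """Lesion disk and distractor ellipses, drawn from the spec seed.

        Returns ``(lesion, distractors)`` where lesion is (cy, cx, r) or None
        and each distractor is (cy, cx, ry, rx, intensity).
        """
        rng = np.random.default_rng(self.seed)
        lesion = None
        if self.lesion:
            cy, cx = self.body_center
            ay, ax = self.body_axes
            r = 0.25 * min(ay, ax)
            ly = cy + rng.uniform(-0.4, 0.4) * ay
            lx = cx + rng.uniform(-0.4, 0.4) * ax
            lesion = (ly, lx, r)
        distractors = []
        s = self.image_size
        for _ in range(self.n_distractors):
            ry = rng.uniform(6.0, 14.0)
            rx = rng.uniform(6.0, 14.0)
            dy = rng.uniform(ry, s - ry)
            dx = rng.uniform(rx, s - rx)
            intensity = self.body_intensity + self.distractor_offset * rng.choice((-1.0, 1.0))
            distractors.append((dy, dx, ry, rx, float(np.clip(intensity, 0.0, 1.0))))
        return lesion, distractors

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["body_center"] = list(d["body_center"])
        d["body_axes"] = list(d["body_axes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["body_center"] = tuple(d["body_center"])
        d["body_axes"] = tuple(d["body_axes"])
        return cls(**d)


def _ellipse_mask(shape: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape, 0:shape]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _rect_mask(shape: int, y0: float, y1: float, x0: float, x1: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape, 0:shape]
    return (yy >= y0) & (yy < y1) & (xx >= x0) & (xx < x1)


def generate_phantom(spec: PhantomSpec) -> SlicePair:
    """Rasterize one phantom slice; a pure function of ``spec``.

    The mask is body ∪ processes ∪ lesion; distractor pixels are painted
    only where the mask is background, so they are disjoint from the
    foreground by construction.
    """
    s = spec.image_size
    cy, cx = spec.body_center
    ay, ax = spec.body_axes

    mask = _ellipse_mask(s, cy, cx, ay, ax)
    for rect in spec.process_rects():
        mask |= _rect_mask(s, *rect)
    lesion, distractors = spec.derived_features()
    lesion_mask = None
    if lesion is not None:
        ly, lx, r = lesion
        lesion_mask = _ellipse_mask(s, ly, lx, r, r)
        mask |= lesion_mask

    image = np.full((s, s), spec.background, dtype=np.float32)
    for dy, dx, ry, rx, intensity in distractors:
        blob = _ellipse_mask(s, dy, dx, ry, rx) & ~mask
        image[blob] = intensity
    image[mask] = spec.body_intensity
    if lesion_mask is not None:
        image[lesion_mask] = min(spec.body_intensity + spec.lesion_boost, 1.0)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape).astype(np.float32)
    image = np.clip(image, 0.0, 1.0)
    return SlicePair(image, mask.astype(np.uint8), f"phantom-{spec.seed}", 0)


# ---------------------------------------------------------------------------
# dataset profiles
# ---------------------------------------------------------------------------

# mixture proportions of the mixed profile (deterministic allocation)
PROFILES = {
    "easy": None,
    "interference": None,
    "lesion": None,
    "mixed": {"easy": 0.4, "interference": 0.3, "lesion": 0.3},
}


def _random_spec(kind: str, rng: np.random.Generator) -> PhantomSpec:
    size = 256
    ay = rng.uniform(24.0, 36.0)
    ax = rng.uniform(34.0, 50.0)
    base = dict(
        image_size=size,
        body_center=(float(rng.uniform(120.0, 160.0)), float(rng.uniform(112.0, 144.0))),
        body_axes=(float(ay), float(ax)),
        body_intensity=float(rng.uniform(0.60, 0.72)),
        n_processes=int(rng.integers(1, 4)),
        process_length=float(rng.uniform(20.0, 32.0)),
        process_width=float(rng.uniform(6.0, 10.0)),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
    if kind == "easy":
        base.update(n_distractors=0, lesion=False, noise_sigma=float(rng.uniform(0.005, 0.015)))
    elif kind == "interference":
        base.update(n_distractors=int(rng.integers(1, 4)),
                    distractor_offset=float(rng.uniform(0.01, 0.05)),
                    lesion=False, noise_sigma=float(rng.uniform(0.01, 0.02)))
    elif kind == "lesion":
        base.update(n_distractors=0, lesion=True,
                    lesion_boost=float(rng.uniform(0.2, 0.3)),
                    noise_sigma=float(rng.uniform(0.01, 0.02)))
    else:
        raise ConfigurationError(f"unknown phantom kind {kind!r}")
    return PhantomSpec(**base)


def _mixture_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation: counts sum to n and match proportions."""
    raw = {k: n * p for k, p in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def generate_dataset(n: int, profile: str = "mixed", seed: int = 0):
    """Generate ``n`` phantom slice pairs plus a replayable manifest.

    The manifest records the profile, seed and every :class:`PhantomSpec`;
    regenerating from the manifest reproduces the dataset bit for bit.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if profile not in PROFILES:
        raise ConfigurationError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    rng = np.random.default_rng(seed)
    if profile == "mixed":
        counts = _mixture_counts(n, PROFILES["mixed"])
        kinds = [k for k in ("easy", "interference", "lesion") for _ in range(counts[k])]
    else:
        kinds = [profile] * n
    specs = [_random_spec(k, rng) for k in kinds]
    pairs = [generate_phantom(sp) for sp in specs]
    manifest = {
        "profile": profile, "seed": seed, "n": n,
        "specs": [dict(kind=k, **sp.to_dict()) for k, sp in zip(kinds, specs)],
    }
    return pairs, manifest


def generate_phantom_volume(n_slices: int, profile: str = "easy", seed: int = 0):
    """Stack phantom slices into a (z,y,x) volume with 1 mm isotropic meta.

    Intensities are scaled to a CT-like range so the volume can exercise the
    windowing/normalization pipeline; labels are the stacked binary masks.
    """
    pairs, _ = generate_dataset(n_slices, profile=profile, seed=seed)
    vol = np.stack([p.image for p in pairs]).astype(np.float32)
    labels = np.stack([p.mask for p in pairs]).astype(np.uint8)
    hu = vol * 1400.0 - 200.0  # map [0,1] onto the default HU window
    return hu, labels, VolumeMeta(spacing=(1.0, 1.0, 1.0), dtype="float32")


def write_dataset(pairs, manifest, out_dir) -> None:
    """Write image/mask PNG pairs and the JSON manifest to a directory."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(pairs):
        iio.imwrite(out / f"img_{i:04d}.png", (p.image * 255).astype(np.uint8))
        iio.imwrite(out / f"mask_{i:04d}.png", (p.mask * 255).astype(np.uint8))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
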