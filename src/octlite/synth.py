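"""Seeded generator of synthetic OCT-like B-scans.

Real retinal B-scans show a bright, gently curved multi-layer band (the
neurosensory retina) over a dark vitreous/choroid background, corrupted by
multiplicative speckle. The generator emulates exactly that much structure —
enough for augmentation, training and evaluation code to be exercised end to
end without any downloaded data — plus one class-specific lesion:

* ``NORMAL`` — clean layered band, no lesion.
* ``DME``    — one or more dark fluid cavities inside the band (edema).
* ``DRUSEN`` — several small bright bumps riding on the lowest band
  (sub-RPE deposits).
* ``CNV``    — one large, irregular hyperreflective mass beneath the band
  (neovascular membrane).

Every image is a pure function of ``(spec.seed, class_label, index)``: the
same triple always yields a byte-identical pixel grid. The speckle model is a
clipped multiplicative gamma field — deliberately simple, not a physical
device simulation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .constants import CLASS_ORDER, JPEG_QUALITY, class_index

__all__ = [
    "SyntheticSpec",
    "ImageSample",
    "generate_bscan",
    "write_dataset",
]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    Attributes
    ----------
    image_height, image_width:
        Pixel dimensions of generated scans; at least 32 each. The default
        256x256 mimics real archives whose images are larger than the
        128x128 model input, so the loader's resize step is exercised.
    n_per_class:
        Number of images generated per class.
    noise_level:
        Speckle strength in [0, 1]; 0 disables speckle entirely.
    seed:
        Base seed; combined with (class, index) per image.
    class_list:
        Ordered class labels; defaults to the canonical four.
    """

    image_height: int = 256
    image_width: int = 256
    n_per_class: int = 10
    noise_level: float = 0.3
    seed: int = 0
    class_list: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image dimensions must be at least 32 pixels")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class ImageSample:
    """One synthetic B-scan.

    ``lesion_box`` is ``(row0, col0, row1, col1)``, 0-based and half-open,
    bounding the inserted lesion; ``None`` for NORMAL scans.
    """

    pixels: np.ndarray  # uint8, (H, W)
    label: str
    lesion_box: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint8 or self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D uint8 array")
        if self.lesion_box is not None:
            r0, c0, r1, c1 = self.lesion_box
            h, w = self.pixels.shape
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"lesion_box {self.lesion_box} outside image {h}x{w}")


# Reflectivity of the stacked retinal sub-layers, top to bottom. The last
# entry is the brightest (RPE-like) band that drusen bumps sit on.
_LAYER_LUT = np.array([185.0, 120.0, 165.0, 95.0, 150.0, 215.0])
_BACKGROUND = 14.0


def _rng_for(spec: SyntheticSpec, label: str, index: int) -> np.random.Generator:
    # SeedSequence mixing keeps per-image streams independent and stable.
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), class_index(label), int(index)])
    )


def _band_geometry(rng: np.random.Generator, h: int, w: int):
    """Top/bottom row of the retinal band per column, as float arrays (w,)."""
    cols = np.arange(w, dtype=float)
    u = (cols - w / 2.0) / w  # in [-0.5, 0.5]
    center = h * rng.uniform(0.40, 0.52) + h * rng.uniform(-0.06, 0.06) * u
    # Downward-opening parabola: fovea-like dip of a few percent of height.
    center = center + h * rng.uniform(0.05, 0.14) * (u ** 2) * 4.0
    thickness = h * rng.uniform(0.16, 0.24)
    top = center - thickness / 2.0
    bottom = center + thickness / 2.0
    return top, bottom


def _clip_box(r0, c0, r1, c1, h, w):
    r0 = int(max(0, min(r0, h - 1)))
    c0 = int(max(0, min(c0, w - 1)))
    r1 = int(max(r0 + 1, min(r1, h)))
    c1 = int(max(c0 + 1, min(c1, w)))
    return r0, c0, r1, c1


def _ellipse_mask(h, w, cy, cx, ry, rx):
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def generate_bscan(class_label: str, spec: SyntheticSpec, index: int) -> ImageSample:
    """Generate one synthetic B-scan of the given class.

    Deterministic in ``(spec.seed, class_label, index)``. See the module
    docstring for the per-class lesion semantics.

    Raises
    ------
    ValueError
        If the label is unknown or ``index >= spec.n_per_class``.
    """
    if class_label not in spec.class_list:
        raise ValueError(
            f"unknown class label {class_label!r}; expected one of {spec.class_list}"
        )
    if not 0 <= index < spec.n_per_class:
        raise ValueError(f"index {index} out of range for n_per_class={spec.n_per_class}")

    h, w = spec.image_height, spec.image_width
    rng = _rng_for(spec, class_label, index)

    top, bottom = _band_geometry(rng, h, w)
    rr = np.arange(h, dtype=float)[:, None]
    in_band = (rr >= top[None, :]) & (rr < bottom[None, :])
    # Relative depth within the band selects a sub-layer reflectivity.
    t = np.clip((rr - top[None, :]) / (bottom - top)[None, :], 0.0, 1.0 - 1e-9)
    layer_idx = (t * len(_LAYER_LUT)).astype(int)
    img = np.where(in_band, _LAYER_LUT[layer_idx], _BACKGROUND)

    lesion_box: tuple[int, int, int, int] | None = None

    if class_label == "DME":
        n_cavities = int(rng.integers(1, 3))
        boxes = []
        for _ in range(n_cavities):
            cx = rng.uniform(0.2, 0.8) * w
            col = int(np.clip(cx, 0, w - 1))
            depth = rng.uniform(0.35, 0.65)
            cy = top[col] + depth * (bottom[col] - top[col])
            rx = rng.uniform(0.05, 0.11) * w
            ry = rng.uniform(0.20, 0.35) * (bottom[col] - top[col])
            mask = _ellipse_mask(h, w, cy, cx, ry, rx) & in_band
            img[mask] = 28.0
            boxes.append((cy - ry, cx - rx, cy + ry + 1, cx + rx + 1))
        r0 = min(b[0] for b in boxes)
        c0 = min(b[1] for b in boxes)
        r1 = max(b[2] for b in boxes)
        c1 = max(b[3] for b in boxes)
        lesion_box = _clip_box(r0, c0, r1, c1, h, w)
    elif class_label == "DRUSEN":
        n_bumps = int(rng.integers(3, 7))
        centers = np.sort(rng.uniform(0.15, 0.85, size=n_bumps)) * w
        boxes = []
        for cx in centers:
            col = int(np.clip(cx, 0, w - 1))
            rx = rng.uniform(0.015, 0.035) * w
            ry = rng.uniform(0.02, 0.045) * h
            cy = bottom[col] - 1.0  # bump apex rides on the lowest band
            mask = _ellipse_mask(h, w, cy, cx, ry, rx)
            img[mask] = 235.0
            boxes.append((cy - ry, cx - rx, cy + ry + 1, cx + rx + 1))
        r0 = min(b[0] for b in boxes)
        c0 = min(b[1] for b in boxes)
        r1 = max(b[2] for b in boxes)
        c1 = max(b[3] for b in boxes)
        lesion_box = _clip_box(r0, c0, r1, c1, h, w)
    elif class_label == "CNV":
        # One large irregular mass just below the band: a union of
        # overlapping ellipses around a common center.
        cx = rng.uniform(0.3, 0.7) * w
        col = int(np.clip(cx, 0, w - 1))
        cy = bottom[col] + rng.uniform(0.03, 0.08) * h
        mask = np.zeros((h, w), dtype=bool)
        lo_r, lo_c, hi_r, hi_c = h, w, 0.0, 0.0
        for _ in range(int(rng.integers(4, 8))):
            dy = rng.uniform(-0.04, 0.04) * h
            dx = rng.uniform(-0.10, 0.10) * w
            ry = rng.uniform(0.03, 0.07) * h
            rx = rng.uniform(0.05, 0.12) * w
            mask |= _ellipse_mask(h, w, cy + dy, cx + dx, ry, rx)
            lo_r = min(lo_r, cy + dy - ry)
            lo_c = min(lo_c, cx + dx - rx)
            hi_r = max(hi_r, cy + dy + ry + 1)
            hi_c = max(hi_c, cx + dx + rx + 1)
        img[mask] = rng.uniform(190.0, 220.0)
        lesion_box = _clip_box(lo_r, lo_c, hi_r, hi_c, h, w)

    if spec.noise_level > 0:
        # Multiplicative gamma speckle, mean 1; clipped with the signal.
        field = rng.gamma(shape=4.0, scale=0.25, size=(h, w))
        img = img * (1.0 + spec.noise_level * (field - 1.0))

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageSample(pixels=pixels, label=class_label, lesion_box=lesion_box)


def write_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path,
    splits: tuple[int, int, int],
) -> pd.DataFrame:
    """Materialize a synthetic dataset tree ``out_dir/<split>/<CLASS>/*.jpeg``.

    ``splits`` gives (train, val, test) image counts per class and must sum
    to ``spec.n_per_class``; images ``0..train-1`` go to train, the next
    block to val, the rest to test. Returns (and writes, as
    ``out_dir/manifest.csv``) a manifest with columns path, label, split.
    """
    splits = tuple(int(s) for s in splits)
    if len(splits) != 3 or any(s < 0 for s in splits):
        raise ValueError("splits must be three non-negative counts (train, val, test)")
    if sum(splits) != spec.n_per_class:
        raise ValueError(
            f"splits {splits} sum to {sum(splits)}, expected n_per_class={spec.n_per_class}"
        )

    out_dir = Path(out_dir)
    bounds = np.cumsum((0,) + splits)
    rows = []
    for label in spec.class_list:
        for i in range(spec.n_per_class):
            split = next(
                s for k, s in enumerate(("train", "val", "test"))
                if bounds[k] <= i < bounds[k + 1]
            )
            sample = generate_bscan(label, spec, i)
            dest = out_dir / split / label
            dest.mkdir(parents=True, exist_ok=True)
            path = dest / f"{label}-{i:05d}.jpeg"
            Image.fromarray(sample.pixels).save(path, quality=JPEG_QUALITY)
            rows.append({"path": str(path), "label": label, "split": split})

    manifest = pd.DataFrame(rows, columns=["path", "label", "split"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
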