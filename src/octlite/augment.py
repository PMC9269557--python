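"""Image augmentation operators and the 48x materialized schema.

Six basic manipulations are supported — horizontal mirror, small rotations,
anisotropic aspect change, histogram equalization, Gaussian blur and a fixed
3x3 sharpen — composed into an :class:`AugmentationSchema`: an ordered list
of stages, each a set of alternative operators, combined as a Cartesian
product. The default schema is

    {identity, mirror}                                          (2)
  x {rotate -15,-10,-5,+5,+10,+15; aspect 1.15x1.0; 1.0x1.15}   (8)
  x {histogram-equalize; Gaussian blur (5,5); sharpen}          (3)

for exactly 48 outputs per input image, each with the input's shape.
Vertical flips are deliberately absent: they would invert the retinal layer
order and produce anatomically impossible scans.

All operators accept uint8 grayscale images, 2-D ``(H, W)`` or channels-last
``(H, W, C)``, and return uint8 arrays of the same shape.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from PIL import Image

from .constants import CLASS_ORDER, JPEG_QUALITY

__all__ = [
    "AugmentationOp",
    "AugmentationSchema",
    "GaussianKernelSpec",
    "mirror_horizontal",
    "rotate",
    "change_aspect",
    "equalize_histogram",
    "make_gaussian_kernel",
    "gaussian_blur",
    "sharpen",
    "default_schema",
    "apply_op",
    "apply_schema",
    "augment_dataset",
    "expected_augmented_counts",
]

logger = logging.getLogger(__name__)

#: Rotation angles the schema may use (degrees, positive = clockwise).
ALLOWED_ANGLES = frozenset({-15, -10, -5, 0, 5, 10, 15})

#: Fixed sharpening kernel (entries sum to 1, so constants are preserved).
SHARPEN_KERNEL = np.array(
    [[-1.0, -1.0, -1.0], [-1.0, 9.0, -1.0], [-1.0, -1.0, -1.0]]
)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 2-D x channels image, got shape {image.shape}")
    return image


def _as_uint8(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), 0, 255).astype(np.uint8)


def mirror_horizontal(image: np.ndarray) -> np.ndarray:
    """Reflect about the vertical axis (reverse column order)."""
    image = _check_image(image)
    return np.ascontiguousarray(image[:, ::-1])


def rotate(image: np.ndarray, angle_deg: int) -> np.ndarray:
    """Rotate about the image center; positive angles are clockwise.

    The output keeps the input's dimensions; corners revealed by the
    rotation are filled with black (the OCT background), interpolation is
    bilinear. Angles are restricted to multiples of 5 deg in [-15, +15].
    """
    image = _check_image(image)
    if angle_deg not in ALLOWED_ANGLES:
        raise ValueError(
            f"angle {angle_deg} not allowed; must be a multiple of 5 in [-15, 15]"
        )
    if angle_deg == 0:
        return image.copy()
    # scipy's positive angle is counterclockwise in array coordinates.
    out = ndi.rotate(
        image.astype(np.float64),
        angle=-angle_deg,
        axes=(0, 1),
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return _as_uint8(out)


def change_aspect(image: np.ndarray, scale_x: float, scale_y: float) -> np.ndarray:
    """Stretch by (scale_x, scale_y) then center-crop back to the input shape.

    Each scale is either exactly 1.0 (axis untouched) or within
    [1.05, 1.30]; at least one axis must be stretched. Stretch-then-crop
    keeps every schema output at one common shape.
    """
    image = _check_image(image)
    for name, s in (("scale_x", scale_x), ("scale_y", scale_y)):
        if not (s == 1.0 or 1.05 <= s <= 1.30):
            raise ValueError(f"{name}={s} outside 1.0 or [1.05, 1.30]")
    if scale_x == 1.0 and scale_y == 1.0:
        raise ValueError("at least one axis must be stretched")

    zoom = (scale_y, scale_x) + (1.0,) * (image.ndim - 2)
    out = ndi.zoom(image.astype(np.float64), zoom, order=1)
    h, w = image.shape[:2]
    r0 = (out.shape[0] - h) // 2
    c0 = (out.shape[1] - w) // 2
    return _as_uint8(out[r0 : r0 + h, c0 : c0 + w])


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Classic CDF-mapping histogram equalization onto [0, 255].

    The mapping is monotone non-decreasing, so intensity ordering is
    preserved. Multi-channel input is treated as one replicated grayscale
    plane: the first channel is equalized and re-replicated. A constant
    image is returned unchanged (its histogram is a single spike).
    """
    image = _check_image(image)
    plane = image if image.ndim == 2 else image[..., 0]
    if plane.dtype != np.uint8:
        raise ValueError("equalize_histogram expects 8-bit intensities")

    hist = np.bincount(plane.ravel(), minlength=256)
    nonzero = np.flatnonzero(hist)
    if nonzero.size <= 1:
        return image.copy()
    cdf = np.cumsum(hist)
    cdf_min = cdf[nonzero[0]]
    total = plane.size
    lut = np.rint((cdf - cdf_min) / (total - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    eq = lut[plane]
    if image.ndim == 3:
        eq = np.repeat(eq[..., None], image.shape[2], axis=2)
    return eq


@dataclasses.dataclass(frozen=True)
class GaussianKernelSpec:
    """A normalized 2-D Gaussian kernel G(x, y) ∝ exp(-(x²+y²) / 2σ²).

    ``entries[i, j]`` corresponds to offsets ``(y, x) = (i - size//2,
    j - size//2)`` from the kernel center; entries are positive, symmetric
    under x↔-x and y↔-y, and sum to 1.
    """

    sigma: float
    size: int
    entries: np.ndarray


def default_sigma(size: int) -> float:
    """σ used when only a kernel size is given: 0.3·((size−1)/2 − 1) + 0.8.

    This is the conventional size-to-sigma rule for image-smoothing kernels;
    it gives σ = 1.1 for the default 5x5 kernel.
    """
    return 0.3 * ((size - 1) / 2.0 - 1.0) + 0.8


def make_gaussian_kernel(size: int = 5, sigma: float | None = None) -> GaussianKernelSpec:
    """Build a normalized 2-D Gaussian kernel on integer offsets.

    ``size`` must be odd; ``sigma`` defaults to :func:`default_sigma`.
    """
    size = int(size)
    if size < 1 or size % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {size}")
    if sigma is None:
        sigma = default_sigma(size)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = size // 2
    offsets = np.arange(-half, half + 1, dtype=np.float64)
    yy, xx = np.meshgrid(offsets, offsets, indexing="ij")
    g = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / (2.0 * math.pi * sigma**2)
    g /= g.sum()
    return GaussianKernelSpec(sigma=float(sigma), size=size, entries=g)


def gaussian_blur(
    image: np.ndarray,
    kernel_size: tuple[int, int] = (5, 5),
    sigma: float | None = None,
) -> np.ndarray:
    """Smooth with a normalized Gaussian kernel; borders are edge-replicated."""
    image = _check_image(image)
    kh, kw = (int(k) for k in kernel_size)
    if kh % 2 == 0 or kw % 2 == 0 or kh < 1 or kw < 1:
        raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
    if kh == kw:
        kernel = make_gaussian_kernel(kh, sigma).entries
    else:
        # Rectangular case: the 2-D Gaussian is separable, so the outer
        # product of the two 1-D profiles reproduces it exactly.
        def profile(k: int) -> np.ndarray:
            s = sigma if sigma is not None else default_sigma(k)
            off = np.arange(k, dtype=np.float64) - k // 2
            p = np.exp(-(off**2) / (2.0 * s**2))
            return p / p.sum()

        kernel = np.outer(profile(kh), profile(kw))
    out = np.empty(image.shape, dtype=np.float64)
    if image.ndim == 2:
        ndi.correlate(image.astype(np.float64), kernel, output=out, mode="nearest")
    else:
        for ch in range(image.shape[2]):
            ndi.correlate(
                image[..., ch].astype(np.float64), kernel,
                output=out[..., ch], mode="nearest",
            )
    return _as_uint8(out)


def sharpen(image: np.ndarray) -> np.ndarray:
    """Edge sharpening with the fixed 3x3 kernel [[-1,-1,-1],[-1,9,-1],[-1,-1,-1]].

    Borders are edge-replicated and the result is clipped to [0, 255]. The
    kernel sums to 1, so constant images pass through unchanged.
    """
    image = _check_image(image)
    out = np.empty(image.shape, dtype=np.float64)
    if image.ndim == 2:
        ndi.correlate(image.astype(np.float64), SHARPEN_KERNEL, output=out, mode="nearest")
    else:
        for ch in range(image.shape[2]):
            ndi.correlate(
                image[..., ch].astype(np.float64), SHARPEN_KERNEL,
                output=out[..., ch], mode="nearest",
            )
    return _as_uint8(out)


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AugmentationOp:
    """One operator in a schema stage.

    ``kind`` selects the operation; the remaining fields parameterize it
    (``angle_deg`` for rotate, ``scale_x``/``scale_y`` for aspect,
    ``kernel_size``/``sigma`` for gblur). ``identity`` is the explicit no-op
    member of a stage.
    """

    kind: str
    angle_deg: int | None = None
    scale_x: float | None = None
    scale_y: float | None = None
    kernel_size: tuple[int, int] = (5, 5)
    sigma: float | None = None

    _KINDS = ("identity", "mirror", "rotate", "aspect", "histeq", "gblur", "sharpen")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown op kind {self.kind!r}; expected one of {self._KINDS}")
        if self.kind == "rotate":
            if self.angle_deg not in ALLOWED_ANGLES:
                raise ValueError(f"rotate angle {self.angle_deg} not allowed")
        if self.kind == "aspect":
            if self.scale_x is None or self.scale_y is None:
                raise ValueError("aspect requires scale_x and scale_y")

    @property
    def tag(self) -> str:
        """Short deterministic tag used in output filenames."""
        if self.kind == "rotate":
            return f"rot{self.angle_deg:+d}"
        if self.kind == "aspect":
            return f"asp{self.scale_x:.2f}x{self.scale_y:.2f}"
        if self.kind == "gblur":
            return f"gblur{self.kernel_size[0]}"
        return self.kind


def apply_op(image: np.ndarray, op: AugmentationOp) -> np.ndarray:
    """Apply one operator to one image."""
    if op.kind == "identity":
        return _check_image(image).copy()
    if op.kind == "mirror":
        return mirror_horizontal(image)
    if op.kind == "rotate":
        return rotate(image, op.angle_deg)
    if op.kind == "aspect":
        return change_aspect(image, op.scale_x, op.scale_y)
    if op.kind == "histeq":
        return equalize_histogram(image)
    if op.kind == "gblur":
        return gaussian_blur(image, op.kernel_size, op.sigma)
    if op.kind == "sharpen":
        return sharpen(image)
    raise ValueError(f"unknown op kind {op.kind!r}")  # pragma: no cover


@dataclasses.dataclass(frozen=True)
class AugmentationSchema:
    """Ordered stages of alternative operators, combined as a product.

    One output is produced per element of the Cartesian product of the
    stages, applying the chosen operator of each stage in stage order.
    """

    stages: tuple[tuple[AugmentationOp, ...], ...]

    def __post_init__(self) -> None:
        if not self.stages or any(len(s) == 0 for s in self.stages):
            raise ValueError("schema needs at least one non-empty stage")

    @property
    def multiplicity(self) -> int:
        """Number of outputs per input: the product of the stage sizes."""
        return math.prod(len(s) for s in self.stages)


def default_schema() -> AugmentationSchema:
    """The canonical 2 x 8 x 3 = 48-fold schema (see module docstring)."""
    mirror_stage = (AugmentationOp("identity"), AugmentationOp("mirror"))
    geometry_stage = tuple(
        AugmentationOp("rotate", angle_deg=a) for a in (-15, -10, -5, 5, 10, 15)
    ) + (
        AugmentationOp("aspect", scale_x=1.15, scale_y=1.0),
        AugmentationOp("aspect", scale_x=1.0, scale_y=1.15),
    )
    photometric_stage = (
        AugmentationOp("histeq"),
        AugmentationOp("gblur"),
        AugmentationOp("sharpen"),
    )
    return AugmentationSchema(stages=(mirror_stage, geometry_stage, photometric_stage))


class SchemaStageError(RuntimeError):
    """An operator failed inside a schema; names the offending stage."""


def apply_schema(image: np.ndarray, schema: AugmentationSchema) -> list[np.ndarray]:
    """All augmented versions of ``image`` under ``schema``.

    Returns exactly ``schema.multiplicity`` images, ordered lexicographically
    over the stage-choice tuples, each with the input's shape.
    """
    image = _check_image(image)
    outputs = []
    for choices in itertools.product(*schema.stages):
        current = image
        for stage_idx, op in enumerate(choices):
            try:
                current = apply_op(current, op)
            except Exception as exc:
                raise SchemaStageError(
                    f"operator {op.tag!r} failed in stage {stage_idx}: {exc}"
                ) from exc
        outputs.append(current)
    return outputs


def _choice_name(indices: tuple[int, ...]) -> str:
    # Default 3-stage schemas use the mirror/geometry/photometric convention
    # <stem>__m<0|1>_g<idx>_p<idx>; other shapes fall back to s<k><idx> parts.
    if len(indices) == 3:
        return f"m{indices[0]}_g{indices[1]}_p{indices[2]}"
    return "_".join(f"s{k}{i}" for k, i in enumerate(indices))


def augment_dataset(
    manifest: pd.DataFrame,
    schema: AugmentationSchema,
    out_dir: str | Path,
    strict: bool = True,
) -> pd.DataFrame:
    """Materialize every augmented image for the files in ``manifest``.

    ``manifest`` needs columns ``path`` and ``label``. Outputs go to
    ``out_dir/<label>/<stem>__m<i>_g<i>_p<i>.jpeg``. Returns a per-class
    counts table with columns Category, Original, Augmented (the augmented
    count is original x multiplicity). Unreadable inputs are logged and, in
    strict mode, abort the run.
    """
    out_dir = Path(out_dir)
    originals = {c: 0 for c in CLASS_ORDER}
    augmented = {c: 0 for c in CLASS_ORDER}
    skipped = []
    index_tuples = list(itertools.product(*(range(len(s)) for s in schema.stages)))

    for row in manifest.itertuples(index=False):
        path, label = Path(row.path), row.label
        try:
            image = np.asarray(Image.open(path).convert("L"))
        except OSError as exc:
            logger.error("unreadable input %s: %s", path, exc)
            skipped.append(str(path))
            continue
        originals[label] = originals.get(label, 0) + 1
        dest = out_dir / label
        dest.mkdir(parents=True, exist_ok=True)
        outputs = apply_schema(image, schema)
        for indices, out in zip(index_tuples, outputs):
            name = f"{path.stem}__{_choice_name(indices)}.jpeg"
            Image.fromarray(out).save(dest / name, quality=JPEG_QUALITY)
            augmented[label] = augmented.get(label, 0) + 1

    if skipped and strict:
        raise RuntimeError(
            f"{len(skipped)} input file(s) could not be read: {skipped[:5]}"
        )

    labels = [c for c in CLASS_ORDER] + sorted(set(originals) - set(CLASS_ORDER))
    return pd.DataFrame(
        {
            "Category": labels,
            "Original": [originals.get(c, 0) for c in labels],
            "Augmented": [augmented.get(c, 0) for c in labels],
        }
    )


def expected_augmented_counts(
    originals: dict[str, int] | list[int],
    schema: AugmentationSchema | None = None,
) -> dict[str, int] | list[int]:
    """Per-class augmented counts implied by the counting rule (count x multiplicity).

    Pure arithmetic — nothing is materialized. Accepts a dict keyed by class
    or a plain sequence, and returns the same shape.
    """
    m = (schema or default_schema()).multiplicity
    if isinstance(originals, dict):
        return {k: int(v) * m for k, v in originals.items()}
    return [int(v) * m for v in originals]
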