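"""The lightweight CNN model family: layer lists, shapes, parameter audits.

Five depths are defined (3, 5, 7, 9 and 11 convolution layers) with the
per-depth filter widths

    ==========  ===============================================
    3 layers    32, 64, 128
    5 layers    32, 64, 128, 256, 512
    7 layers    32, 32, 64, 64, 128, 256, 512
    9 layers    32, 32, 64, 64, 128, 128, 128, 512, 512
    11 layers   32, 32, 64, 64, 128, 128, 256, 256, 512, 512, 512
    ==========  ===============================================

plus a second 5-layer variant ("v2") that swaps standard convolutions for
depthwise separable ones, widens the head, and is the model whose printed
layer table (kernels 3,3,5,3,5; filters 128,128,128,256,256; pools 3x3 then
2x2 twice; dense 256/128/64/32; softmax over 4 classes) this module
reproduces row by row, parameter count by parameter count
(total 2,552,703 = 2,549,951 trainable + 2,752 batch-norm statistics).

All convolutions are valid (no padding, stride 1); pools use stride equal to
their size. The deeper v1-style models (9 and 11 convolutions) also use
separable convolutions; 3-, 5-(v1) and 7-layer models use standard ones.

Parameter counting rules (bias always present, depthwise multiplier 1):

* standard conv:  k²·c_in·c_out + c_out
* separable conv: k²·c_in + c_in·c_out + c_out
* batch norm:     4·c  (2·c trainable scale/shift + 2·c moving statistics)
* dense:          n_in·n_out + n_out
* pool / dropout / flatten: 0
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .constants import MODEL_INPUT_SHAPE, N_CLASSES

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ModelSummary",
    "FAMILY_FILTERS",
    "build_architecture",
    "small_input_v2",
    "infer_output_shapes",
    "count_parameters",
    "multiplication_cost",
    "summary_table",
]

#: Table of filter widths f1..f11 per family member.
FAMILY_FILTERS: dict[str, tuple[int, ...]] = {
    "3-layer": (32, 64, 128),
    "5-layer": (32, 64, 128, 256, 512),
    "7-layer": (32, 32, 64, 64, 128, 256, 512),
    "9-layer": (32, 32, 64, 64, 128, 128, 128, 512, 512),
    "11-layer": (32, 32, 64, 64, 128, 128, 256, 256, 512, 512, 512),
}

_CONV_KINDS = ("conv2d", "separable_conv2d")


@dataclasses.dataclass(frozen=True)
class LayerSpec:
    """One abstract layer of an architecture.

    ``activation`` on a conv/dense layer means ReLU (or softmax, last layer
    only) applied after the batch normalization that follows the layer, or
    immediately if none follows.
    """

    kind: str
    kernel: int | None = None
    filters: int | None = None
    pool: tuple[int, int] | None = None
    rate: float | None = None
    units: int | None = None
    activation: str | None = None


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """A named, ordered layer list with a fixed input shape (H, W, C)."""

    name: str
    input_shape: tuple[int, int, int]
    layers: tuple[LayerSpec, ...]


@dataclasses.dataclass(frozen=True)
class ModelSummary:
    """Per-layer audit: (kind, output_shape, parameter count) plus totals."""

    rows: tuple[tuple[str, tuple[int, ...], int], ...]
    total: int
    trainable: int
    non_trainable: int


def _sepconv(kernel: int, filters: int) -> LayerSpec:
    return LayerSpec("separable_conv2d", kernel=kernel, filters=filters, activation="relu")


def _conv(kernel: int, filters: int) -> LayerSpec:
    return LayerSpec("conv2d", kernel=kernel, filters=filters, activation="relu")


def _bn() -> LayerSpec:
    return LayerSpec("batch_norm")


def _pool(p: int) -> LayerSpec:
    return LayerSpec("max_pool", pool=(p, p))


def _dropout(rate: float) -> LayerSpec:
    return LayerSpec("dropout", rate=rate)


def _dense(units: int, activation: str = "relu") -> LayerSpec:
    return LayerSpec("dense", units=units, activation=activation)


def _build_v2(input_shape: tuple[int, int, int]) -> tuple[LayerSpec, ...]:
    """The separable-convolution 5-layer v2 stack, exactly as printed."""
    layers: list[LayerSpec] = [
        _sepconv(3, 128), _bn(), _pool(3), _dropout(0.15),
        _sepconv(3, 128), _bn(),
        _sepconv(5, 128), _bn(), _pool(2), _dropout(0.15),
        _sepconv(3, 256), _bn(),
        _sepconv(5, 256), _bn(), _pool(2), _dropout(0.15),
        LayerSpec("flatten"),
        _dense(256), _bn(), _dropout(0.25),
        _dense(128), _bn(), _dropout(0.10),
        _dense(64), _bn(), _dropout(0.10),
        _dense(32), _bn(), _dropout(0.10),
        _dense(N_CLASSES, activation="softmax"),
    ]
    return tuple(layers)


def _conv_groups(filters: tuple[int, ...]) -> list[list[int]]:
    """Group consecutive equal filter widths (the family's block structure)."""
    groups: list[list[int]] = []
    for f in filters:
        if groups and groups[-1][-1] == f:
            groups[-1].append(f)
        else:
            groups.append([f])
    return groups


def _build_v1(
    filters: tuple[int, ...],
    separable: bool,
    input_shape: tuple[int, int, int],
) -> tuple[LayerSpec, ...]:
    """MiniVGG-style v1 stack: conv+BN+ReLU blocks, 2x2 pools between groups.

    A pool is skipped when the remaining valid convolutions would drive a
    spatial dimension non-positive (only the deepest member needs this at
    128x128); the final classifier is dropout 25%, flatten, dense 1024 with
    batch norm, dropout 50%, softmax over the classes.
    """
    make = _sepconv if separable else _conv
    groups = _conv_groups(filters)
    layers: list[LayerSpec] = []
    spatial = min(input_shape[0], input_shape[1])
    remaining = len(filters)
    for gi, group in enumerate(groups):
        for f in group:
            layers += [make(3, f), _bn()]
            spatial -= 2
            remaining -= 1
        if spatial <= 0:
            raise ValueError(
                f"input {input_shape} too small for the {len(filters)}-conv family member"
            )
        # Halving must leave room for the remaining 3x3 valid convolutions.
        if spatial // 2 - 2 * remaining >= 1:
            layers.append(_pool(2))
            spatial //= 2
    layers += [
        _dropout(0.25),
        LayerSpec("flatten"),
        _dense(1024), _bn(), _dropout(0.50),
        _dense(N_CLASSES, activation="softmax"),
    ]
    return tuple(layers)


def build_architecture(
    name: str | int,
    variant: str = "v1",
    input_shape: tuple[int, int, int] = MODEL_INPUT_SHAPE,
) -> ArchitectureSpec:
    """Build a family member by name ('3-layer' ... '11-layer') and variant.

    ``variant`` is ``"v1"`` for every depth; ``"v2"`` exists for the 5-layer
    model only. Raises ``ValueError`` listing the valid options otherwise.
    """
    if isinstance(name, int):
        name = f"{name}-layer"
    name = name.lower()
    if name not in FAMILY_FILTERS:
        raise ValueError(
            f"unknown architecture {name!r}; valid names: {sorted(FAMILY_FILTERS)}"
        )
    if variant not in ("v1", "v2"):
        raise ValueError(f"unknown variant {variant!r}; valid variants: ['v1', 'v2']")
    if variant == "v2":
        if name != "5-layer":
            raise ValueError("variant 'v2' is defined for the 5-layer model only")
        layers = _build_v2(input_shape)
    else:
        separable = name in ("9-layer", "11-layer")
        layers = _build_v1(FAMILY_FILTERS[name], separable, input_shape)
    spec = ArchitectureSpec(name=f"{name}-{variant}", input_shape=input_shape, layers=layers)
    infer_output_shapes(spec)  # fail fast on infeasible geometry
    return spec


def small_input_v2(
    input_shape: tuple[int, int, int] = (32, 32, 3),
    width: int = 32,
) -> ArchitectureSpec:
    """Structure-preserving miniature of the 5-layer v2 for small inputs.

    The full v2 layer table cannot accept a 32x32 input under valid padding
    (the spatial size reaches zero before the last convolution), so this
    variant keeps the conv/BN/pool/dropout ordering and dropout rates but
    shrinks the 5x5 kernels to 3x3, scales filters 128/256 down to
    ``width``/``2*width``, drops the third pool, and uses a 2-layer dense
    head. Intended for desk-scale experiments on synthetic data.
    """
    w2 = 2 * width
    layers: tuple[LayerSpec, ...] = (
        _sepconv(3, width), _bn(), _pool(2), _dropout(0.15),
        _sepconv(3, width), _bn(),
        _sepconv(3, width), _bn(), _pool(2), _dropout(0.15),
        _sepconv(3, w2), _bn(),
        _sepconv(3, w2), _bn(), _dropout(0.15),
        LayerSpec("flatten"),
        _dense(2 * width), _bn(), _dropout(0.25),
        _dense(width), _bn(), _dropout(0.10),
        _dense(N_CLASSES, activation="softmax"),
    )
    spec = ArchitectureSpec(name="5-layer-v2-small", input_shape=input_shape, layers=layers)
    infer_output_shapes(spec)
    return spec


def infer_output_shapes(spec: ArchitectureSpec) -> list[tuple[int, ...]]:
    """Output shape after every layer (channels last, no batch axis).

    Valid-convolution arithmetic: conv out = in − kernel + 1; pool:
    floor(in / pool); flatten multiplies the dims; dense sets (units,).
    Raises ``ValueError`` naming the first layer whose spatial size would
    become non-positive.
    """
    shape: tuple[int, ...] = tuple(spec.input_shape)
    shapes: list[tuple[int, ...]] = []
    for i, layer in enumerate(spec.layers):
        if layer.kind in _CONV_KINDS:
            h, w, _ = shape
            h2, w2 = h - layer.kernel + 1, w - layer.kernel + 1
            if h2 <= 0 or w2 <= 0:
                raise ValueError(
                    f"layer {i} ({layer.kind}, kernel {layer.kernel}) reduces "
                    f"spatial size {h}x{w} to {h2}x{w2}"
                )
            shape = (h2, w2, layer.filters)
        elif layer.kind == "max_pool":
            h, w, c = shape
            ph, pw = layer.pool
            h2, w2 = h // ph, w // pw
            if h2 <= 0 or w2 <= 0:
                raise ValueError(f"layer {i} (max_pool {layer.pool}) empties {h}x{w}")
            shape = (h2, w2, c)
        elif layer.kind == "flatten":
            n = 1
            for d in shape:
                n *= d
            shape = (n,)
        elif layer.kind == "dense":
            shape = (layer.units,)
        elif layer.kind in ("batch_norm", "dropout"):
            pass
        else:
            raise ValueError(f"layer {i}: unknown kind {layer.kind!r}")
        shapes.append(shape)
    return shapes


def _layer_params(layer: LayerSpec, in_shape: tuple[int, ...]) -> tuple[int, int]:
    """(trainable, non_trainable) parameter counts of one layer."""
    if layer.kind == "conv2d":
        c_in = in_shape[-1]
        return layer.kernel**2 * c_in * layer.filters + layer.filters, 0
    if layer.kind == "separable_conv2d":
        c_in = in_shape[-1]
        return layer.kernel**2 * c_in + c_in * layer.filters + layer.filters, 0
    if layer.kind == "batch_norm":
        c = in_shape[-1]
        return 2 * c, 2 * c
    if layer.kind == "dense":
        return in_shape[-1] * layer.units + layer.units, 0
    return 0, 0


def count_parameters(spec: ArchitectureSpec) -> ModelSummary:
    """Audit the parameter count of every layer, closed-form.

    Counting rules are in the module docstring; batch-norm moving statistics
    are the only non-trainable parameters.
    """
    shapes = infer_output_shapes(spec)
    in_shapes = [tuple(spec.input_shape)] + shapes[:-1]
    rows = []
    trainable = non_trainable = 0
    for layer, in_shape, out_shape in zip(spec.layers, in_shapes, shapes):
        t, n = _layer_params(layer, in_shape)
        trainable += t
        non_trainable += n
        rows.append((layer.kind, out_shape, t + n))
    return ModelSummary(
        rows=tuple(rows),
        total=trainable + non_trainable,
        trainable=trainable,
        non_trainable=non_trainable,
    )


def multiplication_cost(kernel_n: int, separable: bool) -> int:
    """Per-position multiply count of an NxN kernel: N² standard, 2·N if
    factorized into Nx1 and 1xN spatially separable passes."""
    if kernel_n < 1:
        raise ValueError("kernel_n must be >= 1")
    return 2 * kernel_n if separable else kernel_n * kernel_n


def summary_table(spec: ArchitectureSpec) -> pd.DataFrame:
    """Model summary as a DataFrame (layer kind, output shape, param count)."""
    summary = count_parameters(spec)
    return pd.DataFrame(
        {
            "layer": [r[0] for r in summary.rows],
            "output_shape": [str(r[1]) for r in summary.rows],
            "params": [r[2] for r in summary.rows],
        }
    )
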