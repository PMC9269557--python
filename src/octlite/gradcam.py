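"""Gradient-weighted class activation maps (Grad-CAM).

For a trained network, a target class c and a convolutional feature map A
with channels k, the channel weights are the spatial means of the gradient
of the pre-softmax class score y_c,

    w_k = mean_{i,j}  dy_c / dA_k[i, j],

and the map is the rectified weighted sum ReLU(sum_k w_k A_k), upsampled
bilinearly to the input size and max-normalized to [0, 1]. Bright regions
mark where the model found evidence for the class — on lesion classes they
should concentrate on the lesion, which is directly checkable on synthetic
scans with known lesion boxes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from PIL import Image

from .arch import infer_output_shapes
from .constants import class_index
from .nn import Network

__all__ = ["GradCAMMap", "grad_cam", "default_cam_layer", "overlay"]


@dataclasses.dataclass(frozen=True)
class GradCAMMap:
    """Heatmap in [0, 1] aligned to input pixels; max is 1 unless degenerate."""

    heatmap: np.ndarray  # (H, W) float32
    target_class: str
    layer: str
    degenerate: bool = False


def _bilinear_resize(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    img = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(img.resize((shape[1], shape[0]), Image.BILINEAR), dtype=np.float32)


def default_cam_layer(network: Network) -> str:
    """Deepest convolutional layer whose feature map still has spatial extent.

    A 1x1 map (possible in heavily pooled miniatures) would upsample to a
    constant heatmap, so such layers are skipped when choosing the default.
    """
    shapes = infer_output_shapes(network.spec)
    conv_shapes = [
        s for ls, s in zip(network.spec.layers, shapes)
        if ls.kind in ("conv2d", "separable_conv2d")
    ]
    for name, shape in zip(
        reversed(network.conv_layer_names), reversed(conv_shapes)
    ):
        if shape[0] > 1 and shape[1] > 1:
            return name
    return network.conv_layer_names[-1]


def grad_cam(
    network: Network,
    image: np.ndarray,
    target_class: str,
    layer: str | None = None,
) -> GradCAMMap:
    """Compute the Grad-CAM heatmap for one preprocessed image.

    ``image`` is float32 ``(H, W, C)`` as fed to the model. ``layer`` names
    a convolutional layer of the network; the default is the deepest one
    with a non-degenerate spatial map (see :func:`default_cam_layer`). An
    all-zero map (no positive evidence) is returned with
    ``degenerate=True`` rather than raised.
    """
    if layer is None:
        layer = default_cam_layer(network)
    elif layer not in network.conv_layer_names:
        raise ValueError(
            f"layer {layer!r} is not a convolutional feature map; "
            f"choose one of {network.conv_layer_names}"
        )
    cls = class_index(target_class)
    x = np.asarray(image, dtype=np.float32)[None]
    activation, grad = network.gradient_wrt_layer(x, cls, layer)
    weights = grad[0].mean(axis=(0, 1))  # (C,)
    cam = np.maximum((activation[0] * weights).sum(axis=-1), 0.0)
    cam = _bilinear_resize(cam, image.shape[:2])
    cam = np.maximum(cam, 0.0)
    peak = float(cam.max())
    if peak <= 0.0:
        return GradCAMMap(
            heatmap=np.zeros(image.shape[:2], dtype=np.float32),
            target_class=target_class,
            layer=layer,
            degenerate=True,
        )
    return GradCAMMap(
        heatmap=(cam / peak).astype(np.float32),
        target_class=target_class,
        layer=layer,
    )


def overlay(
    image: np.ndarray, cam: GradCAMMap, alpha: float = 0.4, cmap: str = "viridis"
) -> np.ndarray:
    """Blend the heatmap over the grayscale image; returns uint8 RGB.

    Uses a perceptually uniform colormap at the given alpha.
    """
    import matplotlib  # local: rendering only

    gray = np.asarray(image, dtype=np.float32)
    if gray.ndim == 3:
        gray = gray[..., 0]
    if gray.max() > 1.0:
        gray = gray / 255.0
    base = np.repeat(gray[..., None], 3, axis=2)
    colors = matplotlib.colormaps[cmap](cam.heatmap)[..., :3]
    blended = (1 - alpha) * base + alpha * colors
    return np.clip(np.rint(blended * 255.0), 0, 255).astype(np.uint8)
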