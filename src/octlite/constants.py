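"""Shared constants: class order, canonical input geometry, filename patterns.

The four-class order is fixed everywhere in the package — one-hot encoding,
confusion-matrix axes, report rows — so that artifacts from different commands
line up without a label map.
"""

from __future__ import annotations

#: Fixed class order used for one-hot encoding, confusion axes and reports.
CLASS_ORDER: tuple[str, ...] = ("CNV", "DME", "DRUSEN", "NORMAL")

#: Number of target classes.
N_CLASSES: int = len(CLASS_ORDER)

#: Canonical model input size (height, width, channels).
MODEL_INPUT_SHAPE: tuple[int, int, int] = (128, 128, 3)

#: Split names recognized in on-disk dataset trees.
SPLITS: tuple[str, ...] = ("train", "val", "test")

#: JPEG quality for all images the package writes (bounds compression
#: artifacts; downstream comparisons are statistical, never byte-level
#: after a re-encode).
JPEG_QUALITY: int = 95


def class_index(label: str) -> int:
    """Index of ``label`` in the fixed class order.

    Raises
    ------
    ValueError
        If the label is not one of the four known classes.
    """
    try:
        return CLASS_ORDER.index(label)
    except ValueError:
        raise ValueError(
            f"unknown class label {label!r}; expected one of {CLASS_ORDER}"
        ) from None
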