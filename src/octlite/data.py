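"""Dataset discovery and image loading for split/CLASS/*.jpeg trees.

The on-disk layout is the public OCT archive convention:
``<root>/<split>/<CLASS>/<name>.jpeg`` with splits train/val/test and the
four fixed classes. Scanning is recursive, case-tolerant on extensions, and
deterministic (lexicographic order), so a rescan of an unchanged tree yields
an identical manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .constants import CLASS_ORDER, SPLITS, class_index

__all__ = ["scan_dataset", "load_image", "load_split", "class_counts"]

logger = logging.getLogger(__name__)

_JPEG_SUFFIXES = {".jpeg", ".jpg"}


def scan_dataset(root_dir: str | Path) -> pd.DataFrame:
    """Discover every JPEG under ``root/<split>/<CLASS>/`` into a manifest.

    Returns a DataFrame with columns path, label, split, sorted
    lexicographically. Missing class directories produce a warning and an
    empty class; a tree with no images at all is an error.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    rows = []
    for split in SPLITS:
        split_dir = root / split
        if not split_dir.is_dir():
            continue
        for label in CLASS_ORDER:
            class_dir = split_dir / label
            if not class_dir.is_dir():
                logger.warning("missing class directory %s", class_dir)
                continue
            for path in sorted(class_dir.rglob("*")):
                if path.suffix.lower() in _JPEG_SUFFIXES and path.is_file():
                    rows.append({"path": str(path), "label": label, "split": split})
    if not rows:
        raise FileNotFoundError(f"no JPEG images found under {root}")
    manifest = pd.DataFrame(rows).sort_values(["split", "label", "path"], kind="stable")
    counts = class_counts(manifest)
    logger.info("scanned %s:\n%s", root, counts.to_string(index=False))
    return manifest.reset_index(drop=True)


def class_counts(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-class image counts in the Category/Count table shape."""
    return pd.DataFrame(
        {
            "Category": list(CLASS_ORDER),
            "Count": [int((manifest["label"] == c).sum()) for c in CLASS_ORDER],
        }
    )


def load_image(path: str | Path, target_size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Decode a JPEG into a float32 ``(H, W, 3)`` tensor in [0, 1].

    Grayscale content is replicated to three channels; resizing is bilinear
    to ``target_size`` (height, width).
    """
    try:
        with Image.open(path) as img:
            gray = img.convert("L").resize(
                (target_size[1], target_size[0]), Image.BILINEAR
            )
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    plane = np.asarray(gray, dtype=np.float32) / 255.0
    return np.repeat(plane[..., None], 3, axis=2)


def load_split(
    root_or_manifest,
    split: str,
    target_size: tuple[int, int] = (128, 128),
) -> tuple[np.ndarray, np.ndarray]:
    """Load one split as ``(X, y)``: float32 images and integer labels."""
    if isinstance(root_or_manifest, pd.DataFrame):
        manifest = root_or_manifest
    else:
        manifest = scan_dataset(root_or_manifest)
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"split {split!r} has no images")
    x = np.stack([load_image(p, target_size) for p in rows["path"]])
    y = np.array([class_index(l) for l in rows["label"]])
    return x, y
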