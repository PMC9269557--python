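"""Training and prediction harness.

Defaults mirror the published training protocol: batch size 32, 10 epochs,
Adam at 0.001 (v1) or 0.002 (v2), categorical cross-entropy, 128x128x3
inputs, softmax over the four classes. The harness always consumes
materialized data (arrays or a directory tree) — augmentation happens ahead
of time, never online — and supports seeded under/over-sampling to a uniform
class distribution (the published balanced set used 7000 images per class).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .arch import ArchitectureSpec
from .constants import CLASS_ORDER, MODEL_INPUT_SHAPE, N_CLASSES, class_index
from .nn import Adam, Network, softmax

__all__ = [
    "TrainConfig",
    "TrainReport",
    "TrainingDiverged",
    "balance_classes",
    "fit",
    "predict",
    "predicted_labels",
]


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters; defaults are the published v-series settings.

    ``learning_rate=None`` resolves to 0.001 for v1-style models and 0.002
    for v2 (by architecture name).
    """

    batch_size: int = 32
    epochs: int = 10
    learning_rate: float | None = None
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    input_size: tuple[int, int, int] = MODEL_INPUT_SHAPE
    seed: int = 0
    balance: str = "none"  # none | undersample | oversample
    balance_target: int = 7000

    def resolve_lr(self, arch_name: str) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 0.002 if "v2" in arch_name else 0.001


@dataclasses.dataclass
class TrainReport:
    """Per-epoch curves plus the trained network and the config used."""

    history: pd.DataFrame  # columns: epoch, loss, accuracy[, val_loss, val_accuracy]
    network: Network
    config: TrainConfig

    @property
    def epochs_run(self) -> int:
        return len(self.history)


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the partial report."""

    def __init__(self, message: str, report: TrainReport) -> None:
        super().__init__(message)
        self.report = report


def balance_classes(
    manifest: pd.DataFrame, mode: str, target: int, seed: int
) -> pd.DataFrame:
    """Resample a manifest to exactly ``target`` rows per class.

    ``undersample`` draws without replacement (every class must have at
    least ``target`` rows); ``oversample`` draws with replacement. The
    result is deterministic per seed; ``mode='none'`` returns a copy.
    """
    if mode == "none":
        return manifest.copy()
    if mode not in ("undersample", "oversample"):
        raise ValueError(f"unknown balance mode {mode!r}")
    if target < 1:
        raise ValueError("balance target must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    for label in CLASS_ORDER:
        rows = manifest[manifest["label"] == label]
        if mode == "undersample":
            if len(rows) < target:
                raise ValueError(
                    f"class {label} has {len(rows)} samples, cannot undersample to {target}"
                )
            idx = rng.choice(len(rows), size=target, replace=False)
        else:
            if len(rows) == 0:
                raise ValueError(f"class {label} has no samples to oversample")
            idx = rng.choice(len(rows), size=target, replace=True)
        parts.append(rows.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((len(labels), N_CLASSES), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _as_arrays(data, input_size) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) arrays or a dataset directory/manifest."""
    if isinstance(data, (str, Path)):
        from .data import load_split  # deferred: avoids import cycle at module load

        return load_split(data, "train", target_size=input_size[:2])
    x, y = data
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        y = np.array([class_index(str(l)) for l in y])
    return x, y.astype(int)


def fit(
    architecture: ArchitectureSpec,
    data,
    config: TrainConfig | None = None,
    validation=None,
) -> TrainReport:
    """Train a model on materialized data.

    ``data`` is either a dataset root directory (its ``train`` split is
    used) or a tuple ``(X, y)`` of float32 images in [0, 1], shaped
    ``(N, H, W, C)`` matching the architecture input, with integer or string
    labels. Minimizes categorical cross-entropy with Adam; the seed governs
    weight initialization, shuffling and dropout. Raises
    :class:`TrainingDiverged` (with the partial report attached) on a
    non-finite loss.
    """
    config = config or TrainConfig()
    x, y = _as_arrays(data, architecture.input_shape)
    if x.shape[1:] != tuple(architecture.input_shape):
        raise ValueError(
            f"data shape {x.shape[1:]} does not match architecture input "
            f"{architecture.input_shape}"
        )
    present = np.bincount(y, minlength=N_CLASSES)
    if (present == 0).any():
        missing = [CLASS_ORDER[i] for i in np.flatnonzero(present == 0)]
        raise ValueError(f"training data has empty class(es): {missing}")
    y_onehot = _one_hot(y)

    net = Network(architecture, seed=config.seed)
    opt = Adam(net, lr=config.resolve_lr(architecture.name))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    records = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(x))
        losses, correct = [], 0
        for start in range(0, len(x), config.batch_size):
            sel = order[start : start + config.batch_size]
            loss = net.train_step(x[sel], y_onehot[sel])
            if not np.isfinite(loss):
                partial = TrainReport(
                    history=pd.DataFrame(records), network=net, config=config
                )
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size}",
                    partial,
                )
            opt.step()
            losses.append(loss * len(sel))
        probs = net.predict_proba(x, batch_size=max(config.batch_size, 64))
        correct = int((probs.argmax(axis=1) == y).sum())
        row = {
            "epoch": epoch + 1,
            "loss": float(np.sum(losses) / len(x)),
            "accuracy": correct / len(x),
        }
        if validation is not None:
            vx, vy = _as_arrays(validation, architecture.input_shape)
            vp = net.predict_proba(vx)
            row["val_loss"] = float(
                -np.mean(np.log(vp[np.arange(len(vy)), vy] + 1e-12))
            )
            row["val_accuracy"] = float((vp.argmax(axis=1) == vy).mean())
        records.append(row)

    return TrainReport(history=pd.DataFrame(records), network=net, config=config)


def predict(network: Network, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Per-image class probabilities over (CNV, DME, DRUSEN, NORMAL).

    Each row sums to 1 (within float tolerance); order is preserved.
    Raises ``ValueError`` if the image shape does not match the network
    input.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    expected = tuple(network.spec.input_shape)
    if images.shape[1:] != expected:
        raise ValueError(
            f"images have shape {images.shape[1:]}, expected input size {expected}"
        )
    return network.predict_proba(images, batch_size=batch_size)


def predicted_labels(probs: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Argmax labels (ties break to the lowest class index) and confidences."""
    idx = probs.argmax(axis=1)
    return [CLASS_ORDER[i] for i in idx], probs.max(axis=1)
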