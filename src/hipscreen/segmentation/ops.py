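"""Shared segmentation operations: preprocessing, DICE loss, grouped splits."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize

from ..errors import DegenerateInputError, ValidationError
from ..phantom import LabelMask

FOREGROUND_CLASSES = (1, 2)
DICE_SMOOTHING = 1.0  # pixel-count units; guards the 0/0 empty-class case


def preprocess(image: np.ndarray, input_size_px: int = 256) -> np.ndarray:
    """Normalize an image by its overall mean intensity and resize it square.

    The output has mean 1.0 before resizing (division by the image mean) and
    shape ``(input_size_px, input_size_px)``.  Bilinear resampling; already
    correctly-sized images skip the resampling entirely, so the operation is
    idempotent on normalized, sized inputs.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValidationError("image is empty")
    if not np.isfinite(arr).all():
        raise ValidationError("image contains non-finite values")
    mean = arr.mean()
    if mean <= 0:
        raise DegenerateInputError("image mean intensity is zero; cannot normalize")
    arr = arr / mean
    if arr.shape == (input_size_px, input_size_px):
        return arr
    down = arr.shape[0] > input_size_px or arr.shape[1] > input_size_px
    return resize(arr, (input_size_px, input_size_px), order=1, mode="edge",
                  anti_aliasing=down, preserve_range=True)


def resize_mask(mask: LabelMask | np.ndarray, input_size_px: int) -> np.ndarray:
    """Nearest-neighbor resize of a label mask (labels stay integral)."""
    arr = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if arr.shape == (input_size_px, input_size_px):
        return arr.copy()
    out = resize(arr.astype(float), (input_size_px, input_size_px), order=0,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(np.uint8)


def _one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    return (np.arange(n_classes)[:, None, None] == labels[None]).astype(float)


def dice_per_class(pred_labels: np.ndarray, truth_labels: np.ndarray,
                   classes: Sequence[int] = FOREGROUND_CLASSES,
                   eps: float = DICE_SMOOTHING) -> dict[int, float]:
    """Hard per-class DICE 2|A∩B| / (|A| + |B|) with smoothing ``eps``."""
    out = {}
    for c in classes:
        a = pred_labels == c
        b = truth_labels == c
        out[c] = float((2.0 * np.logical_and(a, b).sum() + eps) / (a.sum() + b.sum() + eps))
    return out


def dice_loss(pred: np.ndarray, truth: LabelMask | np.ndarray,
              eps: float = DICE_SMOOTHING,
              classes: Sequence[int] = FOREGROUND_CLASSES) -> float:
    """Soft DICE loss between per-class probabilities and a label mask.

    ``pred`` has shape (n_classes, H, W) with values in [0, 1]; the loss is
    ``1 - mean_c (2 * sum(p_c * t_c) + eps) / (sum(p_c) + sum(t_c) + eps)``
    over the foreground classes, so a perfect hard prediction scores ~0 and
    disjoint non-empty predictions score ~1.
    """
    truth_labels = truth.labels if isinstance(truth, LabelMask) else np.asarray(truth)
    p = np.asarray(pred, dtype=float)
    if p.ndim != 3:
        raise ValidationError("pred must have shape (n_classes, H, W)")
    if p.shape[1:] != truth_labels.shape:
        raise ValidationError(
            f"pred spatial shape {p.shape[1:]} does not match truth {truth_labels.shape}")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValidationError("pred probabilities must lie in [0, 1]")
    dices = []
    for c in classes:
        t = (truth_labels == c).astype(float)
        pc = p[c]
        dices.append((2.0 * (pc * t).sum() + eps) / (pc.sum() + t.sum() + eps))
    return float(1.0 - np.mean(dices))


def grouped_split(
    subject_ids: Iterable,
    fractions: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
) -> tuple[list, list]:
    """Split subjects (not frames) into train/validation partitions.

    ``subject_ids`` may be one id per frame; the split is computed on the
    unique ids so no subject ever appears on both sides, regardless of how
    many frames each subject contributes.  Deterministic for a given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"split fractions must sum to 1, got {fractions}")
    if min(fractions) <= 0:
        raise ValidationError("both split fractions must be positive")
    unique = sorted(set(subject_ids))
    if len(unique) < 2:
        raise ValidationError("grouped split needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_val = int(round(fractions[1] * len(unique)))
    n_val = min(max(n_val, 1), len(unique) - 1)
    val = [unique[i] for i in sorted(order[:n_val])]
    train = [unique[i] for i in sorted(order[n_val:])]
    return train, val
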