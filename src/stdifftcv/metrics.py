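"""Validation and image-quality measures: Dice, SNR, CNR.

* Dice similarity: ``2 |A ∩ B| / (|A| + |B|)`` between binary masks.
* SNR (dB): ``20 log10(mean_cell / mean_background)``.
* CNR: ``|mean_cell - mean_background| / sd_background`` with the
  population (divide-by-N) standard deviation.

Sequence summaries report mean +- sd over frames.
"""

from __future__ import annotations

import numpy as np

from .io_sequence import ImageFrame, LabelMask

__all__ = ["dice", "snr", "cnr", "sequence_dice", "summary"]


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.binary
    return np.asarray(mask) > 0 if np.asarray(mask).dtype != bool else np.asarray(mask)


def _as_img(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, ImageFrame) else np.asarray(
        frame, dtype=np.float64)


def dice(a, b) -> float:
    """Dice similarity coefficient in [0, 1]; both masks empty -> 1."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def snr(frame, cells) -> float:
    """Signal-to-noise ratio 20 log10(mean_cell / mean_background) in dB."""
    img, m = _as_img(frame), _as_bool(cells)
    if img.shape != m.shape:
        raise ValueError("frame and mask shapes differ")
    if not m.any() or m.all():
        raise ValueError("cell mask must be nonempty and not cover the full frame")
    u_c = float(img[m].mean())
    u_b = float(img[~m].mean())
    if u_b <= 0:
        raise ValueError("background mean must be positive")
    return 20.0 * np.log10(u_c / u_b)


def cnr(frame, cells) -> float:
    """Contrast-to-noise ratio |mean_cell - mean_background| / sd_background."""
    img, m = _as_img(frame), _as_bool(cells)
    if img.shape != m.shape:
        raise ValueError("frame and mask shapes differ")
    if not m.any() or (~m).sum() < 2:
        raise ValueError("need nonempty cells and >= 2 background pixels")
    bg = img[~m]
    sd_b = float(bg.std())  # population sd
    if sd_b == 0:
        raise ValueError("zero background deviation")
    return abs(float(img[m].mean()) - float(bg.mean())) / sd_b


def sequence_dice(pred: list, ref: list) -> np.ndarray:
    """Per-frame binary Dice between predicted and reference mask lists."""
    if len(pred) != len(ref):
        raise ValueError("mask lists differ in length")
    return np.array([dice(p, r) for p, r in zip(pred, ref)])


def summary(values) -> tuple[float, float]:
    """(mean, sd) over frames, sd with ddof=0."""
    v = np.asarray(values, dtype=np.float64)
    return float(v.mean()), float(v.std())
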