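"""Sliding-window semantic overlays of mosaics and Jaccard scoring.

A trained classifier is slid across a large stitched mosaic; every window
position on the stride grid is scored (windows are unit-scaled exactly
like training inputs), each covered pixel accumulates the window's score,
and the final per-pixel value is the accumulated sum divided by the
number of windows covering that pixel. Stride 1 yields the smoothest
overlay; larger strides trade smoothness for speed. Thresholding the mean
score map gives a two-class mask that can be compared to a reference
annotation with the per-class Jaccard index (intersection over union).

Partial windows at the mosaic edge are skipped, so with stride s the
pixels near the right/bottom border may be covered by fewer windows (or,
if the stride exceeds the window, none — such pixels are reported as
background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from thgqc.fcn_model import FCNClassifier
from thgqc.io_manifest import MASK_BACKGROUND, MASK_NORMAL, MASK_TUMOR, Mosaic


@dataclass
class ScoreMap:
    """Per-pixel averaged sliding-window scores with coverage counts.

    ``mean_score`` is defined only where ``coverage_count > 0`` (NaN
    elsewhere) and equals the accumulated score sum divided by the count.
    """

    mean_score: np.ndarray
    coverage_count: np.ndarray
    window_size: int
    stride: int

    @property
    def covered(self) -> np.ndarray:
        return self.coverage_count > 0


@dataclass
class ClasswiseIoU:
    """Jaccard index per tissue class; NaN where the union is empty."""

    iou_normal: float
    iou_tumor: float


def window_positions(shape: tuple[int, int], window: int,
                     stride: int) -> list[tuple[int, int]]:
    """Top-left corners of all full windows on the stride grid."""
    h, w = shape
    return [(i, j)
            for i in range(0, h - window + 1, stride)
            for j in range(0, w - window + 1, stride)]


def _unit_scale(pixels: np.ndarray) -> np.ndarray:
    """Scale integer mosaics to [0,1] by their bit depth; floats pass through."""
    if pixels.dtype == np.uint8:
        return (pixels / 255.0).astype(np.float32)
    if np.issubdtype(pixels.dtype, np.integer):
        return (pixels / 65535.0).astype(np.float32)
    return pixels.astype(np.float32)


def sliding_window_scores(mosaic: Mosaic, model: FCNClassifier,
                          window_size: int = 256, stride: int = 8,
                          batch_windows: int = 64) -> ScoreMap:
    """Score every full window on the stride grid and average per pixel.

    Windows are batched for speed; inference uses running batch-norm
    statistics, so batching cannot change any individual score.
    """
    h, w = mosaic.shape
    if window_size < model.config.min_input_side:
        raise ValueError(
            f"window_size {window_size} below model minimum "
            f"{model.config.min_input_side}"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if h < window_size or w < window_size:
        raise ValueError(
            f"mosaic {h}x{w} smaller than window {window_size}"
        )
    if stride > window_size:
        warnings.warn(
            "stride exceeds window size; coverage will have gaps "
            "(uncovered pixels are reported as undefined)",
            stacklevel=2,
        )
    unit = _unit_scale(mosaic.pixels)
    positions = window_positions((h, w), window_size, stride)
    score_sum = np.zeros((h, w), dtype=np.float64)
    count = np.zeros((h, w), dtype=np.int64)
    for start in range(0, len(positions), batch_windows):
        chunk = positions[start:start + batch_windows]
        batch = np.stack([
            unit[i:i + window_size, j:j + window_size] for i, j in chunk
        ])
        logits = model.forward_logits(batch, train=False)
        scores = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        for (i, j), s in zip(chunk, scores):
            score_sum[i:i + window_size, j:j + window_size] += s
            count[i:i + window_size, j:j + window_size] += 1
    mean = np.full((h, w), np.nan)
    covered = count > 0
    mean[covered] = score_sum[covered] / count[covered]
    return ScoreMap(mean_score=mean, coverage_count=count,
                    window_size=window_size, stride=stride)


def binarize_overlay(score_map: ScoreMap, threshold: float) -> np.ndarray:
    """Class mask from a score map: tumor where mean score >= threshold.

    Covered pixels become normal/tumor; uncovered pixels are background.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    mask = np.full(score_map.mean_score.shape, MASK_BACKGROUND,
                   dtype=np.int64)
    cov = score_map.covered
    tumor = cov & (score_map.mean_score >= threshold)
    mask[cov] = MASK_NORMAL
    mask[tumor] = MASK_TUMOR
    return mask


def jaccard_per_class(pred_mask: np.ndarray,
                      ref_mask: np.ndarray) -> ClasswiseIoU:
    """Set-arithmetic IOU per tissue class (background never counted)."""
    pred_mask = np.asarray(pred_mask)
    ref_mask = np.asarray(ref_mask)
    if pred_mask.shape != ref_mask.shape:
        raise ValueError(
            f"mask shapes differ: {pred_mask.shape} vs {ref_mask.shape}"
        )
    ious = {}
    for cls in (MASK_NORMAL, MASK_TUMOR):
        p = pred_mask == cls
        r = ref_mask == cls
        union = np.sum(p | r)
        ious[cls] = float(np.sum(p & r) / union) if union else float("nan")
    return ClasswiseIoU(iou_normal=ious[MASK_NORMAL],
                        iou_tumor=ious[MASK_TUMOR])
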