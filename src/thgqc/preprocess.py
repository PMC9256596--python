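"""Ingestion standardization: physical pixel size and intensity range.

Every image is resampled to a common pixel size (0.5 µm by default) so
that tissue structures occupy a fixed number of pixels regardless of the
scan program, then "pseudo min-max" normalized: intensities are mapped
linearly from the [0.01, 0.99] quantile range onto the 8-bit range, with
clipping, which fixes the data range while remaining robust to pixel
outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from thgqc.io_manifest import ImageRecord

logger = logging.getLogger(__name__)

#: 4 pooling stages in the classifier require at least 16 px per side
MIN_SIDE = 16


class ImageTooSmallError(ValueError):
    """Raised when resampling would produce an unusably small image."""


@dataclass
class PreprocessConfig:
    """Target pixel size and quantile clip points of the ingestion step."""

    target_pixel_size_um: float = 0.5
    low_quantile: float = 0.01
    high_quantile: float = 0.99

    def __post_init__(self) -> None:
        if not 0 <= self.low_quantile < self.high_quantile <= 1:
            raise ValueError(
                "quantiles must satisfy 0 <= low < high <= 1"
            )
        if not self.target_pixel_size_um > 0:
            raise ValueError("target_pixel_size_um must be > 0")


def standardize_pixel_size(image: ImageRecord,
                           config: PreprocessConfig = PreprocessConfig()
                           ) -> ImageRecord:
    """Resample an image to the configured physical pixel size.

    Output dimensions are ``round(dim * pixel_size / target)``; bilinear
    interpolation, with an anti-aliasing blur when downscaling by more than
    1.5x. An image already at the target size is returned unchanged.
    """
    scale = image.pixel_size_um / config.target_pixel_size_um
    if abs(scale - 1.0) < 1e-12:
        return image
    h = round(image.pixels.shape[0] * scale)
    w = round(image.pixels.shape[1] * scale)
    if min(h, w) < MIN_SIDE:
        raise ImageTooSmallError(
            f"resampling to {config.target_pixel_size_um} um/px would give "
            f"{h}x{w} px (minimum side is {MIN_SIDE})"
        )
    out = resize(
        image.pixels.astype(np.float64),
        (h, w),
        order=1,
        anti_aliasing=scale < 1 / 1.5,
        preserve_range=True,
    )
    top = 2**image.bit_depth - 1
    out = np.clip(np.rint(out), 0, top).astype(image.pixels.dtype)
    return image.with_pixels(out, pixel_size_um=config.target_pixel_size_um)


def pseudo_minmax_to_8bit(image: ImageRecord,
                          config: PreprocessConfig = PreprocessConfig()
                          ) -> ImageRecord:
    """Quantile-clipped linear rescale to 8-bit.

    With q_lo, q_hi the configured quantiles of the pixel values (linear
    interpolation between order statistics), the output is
    ``round(clip((x - q_lo) / (q_hi - q_lo), 0, 1) * 255)``. A constant
    image (q_hi == q_lo) maps to all zeros with a logged warning.
    """
    x = image.pixels.astype(np.float64)
    q_lo, q_hi = np.quantile(x, [config.low_quantile, config.high_quantile])
    if q_hi == q_lo:
        logger.warning(
            "pseudo min-max normalization of a constant image (value %g); "
            "output is all zeros", q_lo,
        )
        out = np.zeros_like(x, dtype=np.uint8)
    else:
        scaled = np.clip((x - q_lo) / (q_hi - q_lo), 0.0, 1.0)
        out = np.floor(scaled * 255.0 + 0.5).astype(np.uint8)
    return image.with_pixels(out, bit_depth=8)


def preprocess_stack(stack, config: PreprocessConfig = PreprocessConfig(),
                     per_stack_quantiles: bool = False):
    """Normalize a z-stack slice by slice, or with shared stack quantiles.

    Per-image normalization (the default) treats each slice like any 2-D
    image; ``per_stack_quantiles`` computes the clip points once over all
    slices, preserving relative brightness across depth (deep slices then
    stay dark instead of being stretched to full range).
    """
    from thgqc.io_manifest import ZStack

    slices = [standardize_pixel_size(s, config) for s in stack.slices]
    if not per_stack_quantiles:
        return ZStack([pseudo_minmax_to_8bit(s, config) for s in slices],
                      depth_step_um=stack.depth_step_um)
    pooled = np.concatenate([s.pixels.ravel() for s in slices]).astype(
        np.float64)
    q_lo, q_hi = np.quantile(pooled, [config.low_quantile,
                                      config.high_quantile])
    out = []
    for s in slices:
        if q_hi == q_lo:
            logger.warning("per-stack normalization of a constant stack")
            pixels = np.zeros_like(s.pixels, dtype=np.uint8)
        else:
            scaled = np.clip((s.pixels - q_lo) / (q_hi - q_lo), 0.0, 1.0)
            pixels = np.floor(scaled * 255.0 + 0.5).astype(np.uint8)
        out.append(s.with_pixels(pixels, bit_depth=8))
    return ZStack(out, depth_step_um=stack.depth_step_um)


def preprocess_image(image: ImageRecord,
                     config: PreprocessConfig = PreprocessConfig()
                     ) -> ImageRecord:
    """Full ingestion: pixel-size standardization then 8-bit normalization."""
    return pseudo_minmax_to_8bit(standardize_pixel_size(image, config), config)


def to_unit_float(image: ImageRecord) -> np.ndarray:
    """Pixel array scaled to [0, 1] float32, as fed to the classifier."""
    top = 2.0**image.bit_depth - 1.0
    return (image.pixels / top).astype(np.float32)
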