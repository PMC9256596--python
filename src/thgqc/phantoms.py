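"""Synthetic THG-like tissue phantoms with known ground truth.

The renderer emulates the *appearance* of third-harmonic-generation images
of brain tissue — bright curvilinear myelinated fibers on a mid-gray
parenchyma background, dark circular cell bodies with dimly visible nuclei —
not the underlying nonlinear-optics physics. Tumor phantoms differ from
normal ones by an elevated cell-body density, which is the separable signal
a classifier must learn.

Noise model
-----------
Two sources, chosen to reproduce the depth behaviour of real acquisitions:

* **Shot noise** on the detected signal: Gaussian with the variance of a
  Poisson photon count at the field's mean photon rate
  (``photons_per_pixel`` per unit intensity) — the stationary large-count
  approximation, white in the frequency domain, with power proportional
  to the (depth-attenuated) mean signal.
* **Detector noise**: an additive Gaussian floor on top of a dark
  pedestal (``detector_offset``), part white (``noise_sigma``) and part
  spatially correlated (``correlated_noise_sigma`` smoothed over
  ``noise_correlation_um``), emulating analogue amplifier bandwidth.
  Depth-independent.

At shallow depth the white shot noise dominates the high-frequency band, so
the power-spectrum tail is close to exponential; as signal decays with
depth the colored detector floor takes over and the tail becomes a scale
mixture of exponentials with heavier kurtosis. This is what makes tail
kurtosis an increasing function of depth for degraded stacks, and hence a
usable exclusion statistic. Two deliberate departures from per-pixel
physicality keep that statistic clean: shot noise is stationary (per-pixel
Poisson rates modulated by the structure correlate neighbouring spectrum
coefficients and destabilize small-field kurtosis), and the dark pedestal
keeps deep, noise-dominated slices away from the zero clip (rectified
noise whitens the tail and masks the colored floor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from thgqc.io_manifest import (
    LABEL_NORMAL,
    LABEL_TUMOR,
    MASK_NORMAL,
    MASK_TUMOR,
    CaseManifest,
    ImageRecord,
    Mosaic,
    ZStack,
    write_image,
    write_manifest,
)


class PhantomParameterError(ValueError):
    """Raised for phantom parameters outside the plausible regime."""


@dataclass
class PhantomParams:
    """Geometry, optics and noise settings of the tissue phantom.

    Densities are per mm² of field; all lengths in micrometres. The tumor
    density must exceed the normal density — that contrast is the ground
    truth the phantoms encode.
    """

    height: int = 256
    width: int = 256
    pixel_size_um: float = 0.5
    background_level: float = 0.6
    cell_density_normal_per_mm2: float = 300.0
    cell_density_tumor_per_mm2: float = 1200.0
    cell_radius_um: tuple[float, float] = (3.0, 6.0)
    cell_contrast: float = 0.30
    nucleus_contrast: float = 0.45
    fiber_count: int = 5
    fiber_width_um: float = 1.5
    fiber_contrast: float = 0.30
    #: Gaussian PSF sigma applied to the noise-free structure; keeps the
    #: rendered tissue band-limited so the spectrum tail is noise-dominated
    optical_blur_um: float = 0.4
    depth_decay_per_um: float = 0.0
    depth_step_um: float = 10.0
    noise_sigma: float = 0.010
    correlated_noise_sigma: float = 0.035
    noise_correlation_um: float = 0.35
    photons_per_pixel: float = 300.0
    detector_offset: float = 0.08
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cell_density_tumor_per_mm2 <= self.cell_density_normal_per_mm2:
            raise PhantomParameterError(
                "tumor cell density must exceed normal cell density"
            )
        if min(self.cell_density_normal_per_mm2, *self.cell_radius_um,
               self.fiber_width_um, self.pixel_size_um) <= 0:
            raise PhantomParameterError(
                "densities, radii, widths and pixel size must be > 0"
            )
        if not 0 < self.background_level < 1:
            raise PhantomParameterError("background_level must lie in (0, 1)")
        if self.depth_decay_per_um < 0:
            raise PhantomParameterError("depth_decay_per_um must be >= 0")
        if self.height < 16 or self.width < 16:
            raise PhantomParameterError("phantom must be at least 16x16 px")

    @property
    def area_mm2(self) -> float:
        return (self.height * self.pixel_size_um
                * self.width * self.pixel_size_um) / 1e6

    def density_for(self, class_label: str) -> float:
        if class_label == LABEL_TUMOR:
            return self.cell_density_tumor_per_mm2
        if class_label == LABEL_NORMAL:
            return self.cell_density_normal_per_mm2
        raise ValueError(f"unknown class label {class_label!r}")


@dataclass
class DatasetSpec:
    """Shape of a generated multi-case dataset.

    Defaults mirror the real training cohort: 4 histologically normal
    (epilepsy) cases vs. 15 glioma cases, with roughly 10% of images from
    the normal class, and a sizeable fraction of images coming from depth
    stacks (whose deep slices are noise-degraded when
    ``params.depth_decay_per_um > 0``).
    """

    n_normal_cases: int = 4
    n_tumor_cases: int = 15
    images_per_case: tuple[int, int] = (4, 8)
    normal_image_fraction: float = 0.10
    stack_fraction: float = 0.4
    slices_per_stack: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal_cases < 1 or self.n_tumor_cases < 1:
            raise PhantomParameterError(
                "need at least one case per class"
            )
        if not 0 < self.normal_image_fraction < 1:
            raise PhantomParameterError(
                "normal_image_fraction must lie in (0, 1)"
            )
        if not 0 <= self.stack_fraction <= 1:
            raise PhantomParameterError("stack_fraction must lie in [0, 1]")


def _soft_disc(h: int, w: int, cy: float, cx: float, radius: float,
               aa: float = 1.0) -> np.ndarray:
    """Anti-aliased disc coverage in [0,1], computed on a local window."""
    y0 = max(int(cy - radius - 2), 0)
    y1 = min(int(cy + radius + 3), h)
    x0 = max(int(cx - radius - 2), 0)
    x1 = min(int(cx + radius + 3), w)
    out = np.zeros((h, w), dtype=np.float32)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    out[y0:y1, x0:x1] = np.clip((radius - d) / aa + 0.5, 0.0, 1.0)
    return out


def _render_cells(params: PhantomParams, density_per_mm2: float,
                  rng: np.random.Generator,
                  x_weight=None) -> tuple[np.ndarray, np.ndarray]:
    """Dark cell bodies with dim nuclei; returns (signal delta, cell mask).

    ``x_weight``: optional callable mapping x-position (px) to an acceptance
    probability, used for density ramps (inhomogeneous Poisson thinning).
    """
    h, w = params.height, params.width
    r_lo, r_hi = params.cell_radius_um
    mean_r_px = (r_lo + r_hi) / 2 / params.pixel_size_um
    lam = density_per_mm2 * params.area_mm2
    coverage = lam * math.pi * mean_r_px**2 / (h * w)
    if coverage > 0.5:
        raise PhantomParameterError(
            f"cell density implies {coverage:.0%} area coverage (> 50%); "
            "phantom would be unrealistic"
        )
    n = rng.poisson(lam)
    body_cov = np.zeros((h, w), dtype=np.float32)
    nuc_cov = np.zeros((h, w), dtype=np.float32)
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        if x_weight is not None and rng.uniform() > x_weight(cx):
            continue
        radius = rng.uniform(r_lo, r_hi) / params.pixel_size_um
        body = _soft_disc(h, w, cy, cx, radius)
        nucleus = _soft_disc(h, w, cy, cx, radius * 0.45)
        # overlapping dark bodies do not darken further (max coverage),
        # which also keeps the detected signal strictly positive
        np.maximum(body_cov, body, out=body_cov)
        np.maximum(nuc_cov, nucleus, out=nuc_cov)
        mask |= body > 0.5
    # dark body, partially refilled by the dim nucleus
    delta = params.cell_contrast * (params.nucleus_contrast * nuc_cov
                                    - body_cov)
    return delta, mask


def _render_fibers(params: PhantomParams,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Bright curvilinear fibers as smoothed random walks."""
    h, w = params.height, params.width
    canvas = np.zeros((h, w), dtype=np.float32)
    n_steps = int(1.5 * max(h, w))
    for _ in range(params.fiber_count):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        theta = rng.uniform(0, 2 * math.pi)
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.15)
            y += math.sin(theta)
            x += math.cos(theta)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < h and 0 <= ix < w:
                canvas[iy, ix] = 1.0
    sigma_px = params.fiber_width_um / params.pixel_size_um / 2.355
    blurred = gaussian_filter(canvas, sigma=max(sigma_px, 0.5))
    if blurred.max() > 0:
        blurred = blurred / blurred.max()
    delta = params.fiber_contrast * blurred
    mask = blurred > 0.25
    return delta, mask


def _structure_field(params: PhantomParams, class_label: str,
                     rng: np.random.Generator,
                     x_weight=None, density: Optional[float] = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free structure deviation from background, plus masks."""
    d = params.density_for(class_label) if density is None else density
    cell_delta, cell_mask = _render_cells(params, d, rng, x_weight=x_weight)
    if params.fiber_count > 0:
        fiber_delta, fiber_mask = _render_fibers(params, rng)
    else:
        fiber_delta = np.zeros_like(cell_delta)
        fiber_mask = np.zeros_like(cell_mask)
    # optical PSF blur keeps structure band-limited
    sigma_px = params.optical_blur_um / params.pixel_size_um
    delta = gaussian_filter(cell_delta + fiber_delta, sigma=sigma_px)
    return delta, cell_mask, fiber_mask


def _detect(signal: np.ndarray, params: PhantomParams,
            rng: np.random.Generator) -> np.ndarray:
    """Apply shot and detector noise plus dark offset, quantize to 16-bit."""
    signal = np.clip(signal, 0.0, 1.5)
    detected = signal.astype(np.float32)
    if params.photons_per_pixel > 0:
        # stationary Gaussian approximation of photon shot noise at the
        # field-mean rate (see module docstring)
        lam = float(signal.mean()) * params.photons_per_pixel
        shot_sigma = math.sqrt(max(lam, 0.0)) / params.photons_per_pixel
        detected = detected + rng.normal(
            0.0, shot_sigma, signal.shape
        ).astype(np.float32)
    if params.noise_sigma > 0:
        detected = detected + rng.normal(
            0.0, params.noise_sigma, signal.shape
        ).astype(np.float32)
    if params.correlated_noise_sigma > 0:
        corr_px = params.noise_correlation_um / params.pixel_size_um
        raw = rng.normal(0.0, 1.0, signal.shape).astype(np.float32)
        smooth = gaussian_filter(raw, sigma=corr_px)
        std = smooth.std()
        if std > 0:
            detected = detected + params.correlated_noise_sigma * smooth / std
    out = np.clip(params.detector_offset + detected, 0.0, 1.0)
    return np.floor(out * 65535.0 + 0.5).astype(np.uint16)


def render_tissue_image(params: PhantomParams, class_label: str,
                        rng: np.random.Generator,
                        depth_attenuation: float = 1.0,
                        case_id: str = "phantom"
                        ) -> tuple[ImageRecord, np.ndarray, np.ndarray]:
    """Render one 2-D phantom image with its cell and fiber masks.

    ``depth_attenuation`` scales the detected signal (1 at the surface),
    emulating THG signal loss with imaging depth: structure contrast and
    its shot noise shrink together while the detector noise floor is
    unaffected, so SNR drops as attenuation does.
    """
    delta, cell_mask, fiber_mask = _structure_field(params, class_label, rng)
    signal = depth_attenuation * (params.background_level + delta)
    pixels = _detect(signal, params, rng)
    rec = ImageRecord(pixels, params.pixel_size_um, bit_depth=16,
                      case_id=case_id, label=class_label)
    return rec, cell_mask, fiber_mask


def render_zstack(params: PhantomParams, class_label: str, n_slices: int,
                  rng: np.random.Generator, case_id: str = "phantom"
                  ) -> ZStack:
    """Render a depth stack of one field with exponentially decaying contrast.

    The lateral structure is rendered once and shared by all slices (a depth
    scan images one location); slice ``k`` has its detected signal — and so
    its structure contrast — scaled by
    ``exp(-depth_decay_per_um * k * depth_step_um)`` while shot and detector
    noise are sampled fresh per slice, so SNR decreases monotonically with
    depth whenever the decay rate is positive.
    """
    if n_slices < 2:
        raise ValueError("a z-stack needs at least 2 slices")
    delta, _, _ = _structure_field(params, class_label, rng)
    slices = []
    for k in range(n_slices):
        atten = math.exp(-params.depth_decay_per_um * k * params.depth_step_um)
        signal = atten * (params.background_level + delta)
        pixels = _detect(signal, params, rng)
        slices.append(ImageRecord(pixels, params.pixel_size_um, bit_depth=16,
                                  case_id=case_id, depth_index=k,
                                  label=class_label))
    return ZStack(slices, depth_step_um=params.depth_step_um)


def render_boundary_mosaic(params: PhantomParams, rng: np.random.Generator,
                           case_id: str = "phantom-mosaic") -> Mosaic:
    """Render a mosaic whose cell density ramps linearly normal -> tumor.

    The left edge is at the normal density, the right edge at the tumor
    density (inhomogeneous Poisson sampling by thinning). The reference mask
    labels columns left of the density midpoint as normal and right of it
    as tumor, matching a pathologist-style two-region annotation.
    """
    d_lo = params.cell_density_normal_per_mm2
    d_hi = params.cell_density_tumor_per_mm2
    w = params.width

    def x_weight(x: float) -> float:
        frac = min(max(x / max(w - 1, 1), 0.0), 1.0)
        return (d_lo + (d_hi - d_lo) * frac) / d_hi

    delta, _, _ = _structure_field(params, LABEL_TUMOR, rng,
                                   x_weight=x_weight, density=d_hi)
    signal = params.background_level + delta
    pixels = _detect(signal, params, rng)
    mask = np.full((params.height, params.width), MASK_NORMAL, dtype=np.int64)
    mask[:, w // 2:] = MASK_TUMOR
    return Mosaic(pixels, params.pixel_size_um, case_id=case_id,
                  reference_mask=mask)


def _plan_counts(spec: DatasetSpec, rng: np.random.Generator
                 ) -> tuple[list[int], list[int]]:
    """Images per tumor case and per normal case hitting the imbalance target."""
    lo, hi = spec.images_per_case
    tumor_counts = [int(rng.integers(lo, hi + 1))
                    for _ in range(spec.n_tumor_cases)]
    total_tumor = sum(tumor_counts)
    f = spec.normal_image_fraction
    total_normal = max(spec.n_normal_cases,
                       round(f / (1 - f) * total_tumor))
    base, extra = divmod(total_normal, spec.n_normal_cases)
    normal_counts = [base + (1 if i < extra else 0)
                     for i in range(spec.n_normal_cases)]
    return tumor_counts, normal_counts


def generate_dataset_records(
    spec: DatasetSpec, params: PhantomParams
) -> tuple[list[ImageRecord], pd.DataFrame]:
    """Generate a multi-case dataset in memory.

    Returns the rendered images and a manifest-shaped table (image_path
    left relative; filled in by :func:`generate_dataset` when writing to
    disk). RNG streams are spawned per image group from the master seed, so
    generation is deterministic and order-independent.
    """
    master = np.random.SeedSequence(spec.seed)
    rng_plan = np.random.Generator(np.random.PCG64(master.spawn(1)[0]))
    tumor_counts, normal_counts = _plan_counts(spec, rng_plan)

    records: list[ImageRecord] = []
    rows = []
    case_plans = (
        [("epilepsy", LABEL_NORMAL, i, c) for i, c in enumerate(normal_counts)]
        + [("glioma", LABEL_TUMOR, i, c) for i, c in enumerate(tumor_counts)]
    )
    for diagnosis, label, idx, n_images in case_plans:
        case_id = f"{diagnosis}-{idx:02d}"
        case_seq = master.spawn(1)[0]
        rng = np.random.Generator(np.random.PCG64(case_seq))
        n_made = 0
        img_idx = 0
        while n_made < n_images:
            want_stack = (rng.uniform() < spec.stack_fraction
                          and n_images - n_made >= spec.slices_per_stack)
            if want_stack:
                stack = render_zstack(params, label, spec.slices_per_stack,
                                      rng, case_id=case_id)
                for rec in stack:
                    name = f"{case_id}_img{img_idx:03d}_z{rec.depth_index}.tif"
                    records.append(rec)
                    rows.append({
                        "image_path": name, "case_id": case_id,
                        "diagnosis": diagnosis, "split_role": "train",
                        "pixel_size_um": params.pixel_size_um,
                        "depth_index": rec.depth_index,
                    })
                    n_made += 1
                img_idx += 1
            else:
                rec, _, _ = render_tissue_image(params, label, rng,
                                                case_id=case_id)
                name = f"{case_id}_img{img_idx:03d}.tif"
                records.append(rec)
                rows.append({
                    "image_path": name, "case_id": case_id,
                    "diagnosis": diagnosis, "split_role": "train",
                    "pixel_size_um": params.pixel_size_um,
                    "depth_index": None,
                })
                n_made += 1
                img_idx += 1
    return records, pd.DataFrame(rows)


def generate_dataset(spec: DatasetSpec, params: PhantomParams, out_dir,
                     overwrite: bool = False) -> CaseManifest:
    """Render a dataset to ``out_dir`` as TIFFs plus ``manifest.csv``."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    records, table = generate_dataset_records(spec, params)
    for rec, name in zip(records, table["image_path"]):
        write_image(out_dir / name, rec)
    manifest = CaseManifest(table, root=out_dir)
    write_manifest(manifest_path, manifest)
    return manifest
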