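"""Desk-scale experiment recipes: fixed study conditions for CPU runs.

The full-scale study (thousands of 1000x1000 px images, 10 Monte-Carlo
splits, ~120-epoch training runs) is GPU-sized; the package therefore
pins a set of reduced study conditions that preserve the phenomena of
interest while staying trainable on a single CPU:

* ``learnability``  — cleanly separable 48 px phantoms; the classifier
  must reach high validation AUC, and collapse to chance on permuted
  labels.
* ``condition sweep`` — a 96 px dataset whose depth stacks degrade into
  detector noise; exclusion conditions of increasing strictness are
  compared by mean validation AUC (none vs. moderate vs. over-strict).
* ``boundary overlay`` — a normal-to-tumor density-ramp mosaic scored by
  a model trained on the separable phantoms.

Image sizes, densities, epochs and learning rates here are the package's
own desk-scale choices (see docs/methods.md); cell densities are scaled
inversely with field area so a field holds the same expected cell count
as the full-scale defaults, and smaller cell radii keep area coverage
realistic. The quality statistic needs ~100 px fields to be stable (the
kurtosis of 1-2k heavy-tailed power values is noisy below that), hence
the two different phantom sizes.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from thgqc.fcn_model import FCNConfig
from thgqc.io_manifest import LABEL_NORMAL, LABEL_TUMOR, Mosaic
from thgqc.phantoms import (
    PhantomParams,
    render_boundary_mosaic,
    render_tissue_image,
    render_zstack,
)
from thgqc.quality import QualityCondition
from thgqc.training import Sample, TrainConfig

#: separable phantom for learnability/overlay runs: 48 px field at 0.5 um,
#: ~1.5 (normal) vs. ~12 (tumor) cells per field
LEARNABILITY_PARAMS = PhantomParams(
    height=48,
    width=48,
    cell_radius_um=(1.5, 3.0),
    cell_density_normal_per_mm2=2600.0,
    cell_density_tumor_per_mm2=20800.0,
    fiber_count=2,
)

#: sweep phantom: 96 px field; depth stacks decay into the detector noise
#: floor, giving deep slices a heavy-tailed (high-kurtosis) spectrum tail
SWEEP_PARAMS = PhantomParams(
    height=96,
    width=96,
    cell_radius_um=(1.5, 3.0),
    cell_density_normal_per_mm2=1300.0,
    cell_density_tumor_per_mm2=5200.0,
    fiber_count=3,
    depth_decay_per_um=0.06,
    depth_step_um=10.0,
    noise_sigma=0.008,
    correlated_noise_sigma=0.05,
    photons_per_pixel=500.0,
)

#: the three sweep rules: keep everything; exclude the noise-dominated
#: tail (moderate); exclude everything but the very cleanest images
#: (over-strict, the >80%-exclusion pathology)
SWEEP_CONDITIONS = (
    QualityCondition(None, None),
    QualityCondition(0.2, 13.0),
    QualityCondition(0.2, 8.5),
)

#: desk-scale optimizer settings: few steps, so a larger learning rate and
#: fast-adapting batch-norm statistics
DESK_FCN = FCNConfig(bn_momentum=0.5)
DESK_TRAIN = TrainConfig(learning_rate=0.02, max_epochs=10, batch_size=16)


def _jitter_params(params: PhantomParams, rng: np.random.Generator,
                   variation: float) -> PhantomParams:
    """Case-level rendering variation (inter-patient heterogeneity).

    Each case gets its own background level, cell contrast and density
    scale; the tumor/normal density ratio is preserved. This is what
    makes generalization require a diversity of training *cases*, as with
    real patients.
    """
    if variation <= 0:
        return params
    u = lambda: 1.0 + rng.uniform(-variation, variation)
    return replace(
        params,
        background_level=min(max(params.background_level * u(), 0.2), 0.8),
        cell_contrast=params.cell_contrast * u(),
        cell_density_normal_per_mm2=params.cell_density_normal_per_mm2 * u(),
        cell_density_tumor_per_mm2=params.cell_density_tumor_per_mm2 * u(),
    )


def _case_samples(params: PhantomParams, label: str, case_id: str,
                  n_singles: int, n_stacks: int, slices_per_stack: int,
                  rng: np.random.Generator,
                  case_variation: float = 0.0) -> list[Sample]:
    params = _jitter_params(params, rng, case_variation)
    out = []
    k = 0
    for _ in range(n_singles):
        rec, _, _ = render_tissue_image(params, label, rng, case_id=case_id)
        out.append(Sample((rec.pixels / 65535.0).astype(np.float32),
                          1 if label == LABEL_TUMOR else 0,
                          case_id, f"{case_id}/{k}"))
        k += 1
    for _ in range(n_stacks):
        stack = render_zstack(params, label, slices_per_stack, rng,
                              case_id=case_id)
        for rec in stack:
            out.append(Sample((rec.pixels / 65535.0).astype(np.float32),
                              1 if label == LABEL_TUMOR else 0,
                              case_id, f"{case_id}/{k}"))
            k += 1
    return out


def learnability_samples(seed: int, n_normal_cases: int = 3,
                         n_tumor_cases: int = 6,
                         images_per_case: int = 6) -> list[Sample]:
    """Cleanly separable single-shot phantoms for the learnability check."""
    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    for i in range(n_normal_cases):
        samples += _case_samples(LEARNABILITY_PARAMS, LABEL_NORMAL,
                                 f"epilepsy-{i:02d}", images_per_case, 0, 0,
                                 rng)
    for i in range(n_tumor_cases):
        samples += _case_samples(LEARNABILITY_PARAMS, LABEL_TUMOR,
                                 f"glioma-{i:02d}", images_per_case, 0, 0,
                                 rng)
    return samples


def sweep_samples(seed: int, n_normal_cases: int = 4, n_tumor_cases: int = 5,
                  singles_per_case: int = 3, stacks_per_case: int = 1,
                  slices_per_stack: int = 6,
                  case_variation: float = 0.25) -> list[Sample]:
    """Noise-degraded heterogeneous dataset for the condition sweep.

    Every case contributes clean single shots plus one depth stack whose
    deeper slices sink below the noise floor while keeping the case's
    weak label — the mislabeled-noise contamination the exclusion rule is
    meant to remove. Cases differ in background, contrast and density
    scale (``case_variation``), so models must see a diversity of cases
    to generalize; an over-strict rule that strands training on a couple
    of cases fails on held-out cases even when its images are clean.
    """
    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    for i in range(n_normal_cases):
        samples += _case_samples(SWEEP_PARAMS, LABEL_NORMAL,
                                 f"epilepsy-{i:02d}", singles_per_case,
                                 stacks_per_case, slices_per_stack, rng,
                                 case_variation=case_variation)
    for i in range(n_tumor_cases):
        samples += _case_samples(SWEEP_PARAMS, LABEL_TUMOR,
                                 f"glioma-{i:02d}", singles_per_case,
                                 stacks_per_case, slices_per_stack, rng,
                                 case_variation=case_variation)
    return samples


def permute_labels(samples: list[Sample], seed: int) -> list[Sample]:
    """Random label permutation (the no-signal control)."""
    rng = np.random.default_rng(seed)
    labels = rng.permutation([s.label for s in samples])
    return [s._replace(label=int(l)) for s, l in zip(samples, labels)]


def boundary_mosaic(seed: int, height: int = 256, width: int = 512) -> Mosaic:
    """Density-ramp mosaic matching the learnability phantom appearance."""
    params = replace(LEARNABILITY_PARAMS, height=height, width=width)
    return render_boundary_mosaic(params, np.random.default_rng(seed))
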