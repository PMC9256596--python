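"""Frequency-domain image-quality statistics and kurtosis-based exclusion.

Noise added in the image domain raises the variety and intensity of the
high spatial frequencies. The quality statistic used here summarizes the
distribution of power-spectrum values in the top fraction of the radial
frequency range ("the tail"): for each image the 2-D discrete Fourier
transform of the mean-subtracted pixels is taken, every coefficient is
assigned a radial frequency normalized so that 1 equals the Nyquist
frequency along the shorter image axis, and the tail collects the power of
all coefficients at or above ``1 - freq_frac`` (DC always excluded).

Seven descriptive statistics of the tail are computed; the exclusion rule
acts on the **Pearson kurtosis** (fourth standardized moment, 3 for a
Gaussian): a training image is excluded when its tail kurtosis exceeds the
configured cutoff. The rule is applied to training data only — a held-out
test set is never filtered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from thgqc.io_manifest import ImageRecord, ZStack

#: the seven sweep conditions studied for training-set selection:
#: (freq_frac, kurtosis_cutoff), with (None, None) meaning "no exclusion"
DEFAULT_CONDITIONS: tuple[tuple[Optional[float], Optional[float]], ...] = (
    (None, None),
    (0.4, 10.0), (0.4, 5.0),
    (0.2, 10.0), (0.2, 5.0),
    (0.1, 10.0), (0.1, 5.0),
)


@dataclass(frozen=True)
class SpectrumTail:
    """High-frequency power values of one image's spectrum."""

    freq_frac: float
    power_values: np.ndarray

    def __post_init__(self) -> None:
        if not 0 < self.freq_frac <= 1:
            raise ValueError("freq_frac must lie in (0, 1]")
        if self.power_values.size == 0:
            raise ValueError("empty spectrum tail")


@dataclass(frozen=True)
class TailStats:
    """The seven descriptive statistics of a spectrum tail.

    Moments are population moments; kurtosis is Pearson (m4/m2², normal=3)
    and skewness m3/m2^1.5. A zero-variance tail yields NaN sentinels for
    kurtosis and skewness.
    """

    mean: float
    inverse_mean: float
    std: float
    inverse_std: float
    coefficient_of_variation: float
    kurtosis: float
    skewness: float


@dataclass(frozen=True)
class QualityCondition:
    """A (frequency-fraction, kurtosis-cutoff) exclusion rule.

    Both fields ``None`` means "keep everything" (the unfiltered baseline);
    otherwise both must be set.
    """

    freq_frac: Optional[float] = None
    kurtosis_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.freq_frac is None) != (self.kurtosis_cutoff is None):
            raise ValueError(
                "freq_frac and kurtosis_cutoff must both be set or both None"
            )
        if self.freq_frac is not None and not 0 < self.freq_frac <= 1:
            raise ValueError("freq_frac must lie in (0, 1]")
        if self.kurtosis_cutoff is not None and not self.kurtosis_cutoff > 0:
            raise ValueError("kurtosis_cutoff must be > 0")

    @property
    def is_null(self) -> bool:
        return self.freq_frac is None

    def __str__(self) -> str:
        if self.is_null:
            return "none-none"
        return f"{self.freq_frac:g}-{self.kurtosis_cutoff:g}"


@dataclass
class QualityReport:
    """Per-image kurtosis and exclusion flags under one condition."""

    condition: QualityCondition
    table: pd.DataFrame  # columns: image_id, kurtosis, excluded

    @property
    def n_images(self) -> int:
        return len(self.table)

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_images if self.n_images else 0.0

    @property
    def excluded_ids(self) -> set:
        return set(self.table.loc[self.table["excluded"], "image_id"])


def _as_array(image) -> np.ndarray:
    if isinstance(image, ImageRecord):
        return image.pixels.astype(np.float64)
    return np.asarray(image, dtype=np.float64)


def radial_frequency_grid(shape: tuple[int, int]) -> np.ndarray:
    """Normalized radial frequency of every DFT coefficient.

    Frequencies in cycles/pixel from :func:`numpy.fft.fftfreq`; the radius
    is normalized so 1.0 is the Nyquist frequency (0.5 cycles/pixel) along
    the shorter axis. Corner coefficients of a square image reach sqrt(2).
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    return np.hypot(fy, fx) / 0.5


def power_spectrum_tail(image, freq_frac: float,
                        log_power: bool = False) -> SpectrumTail:
    """Power values of the top ``freq_frac`` of the radial frequency range.

    The image is mean-subtracted before the FFT so no DC/windowing energy
    can leak into extreme tails; the DC coefficient itself is always
    excluded. ``log_power`` switches to log10(power) values (with a small
    floor), offered for cross-checking; raw power is the default.
    """
    x = _as_array(image)
    if x.ndim != 2 or min(x.shape) < 16:
        raise ValueError("image must be 2-D and at least 16x16")
    if not np.isfinite(x).all():
        raise ValueError("image contains non-finite pixels")
    if not 0 < freq_frac <= 1:
        raise ValueError("freq_frac must lie in (0, 1]")
    x = x - x.mean()
    power = np.abs(np.fft.fft2(x)) ** 2
    r = radial_frequency_grid(x.shape)
    sel = r >= (1.0 - freq_frac)
    sel[0, 0] = False  # DC
    values = power[sel]
    if values.size == 0:
        raise ValueError(f"freq_frac {freq_frac} selects no coefficients")
    if log_power:
        floor = np.finfo(np.float64).tiny
        values = np.log10(np.maximum(values, floor))
    return SpectrumTail(freq_frac=freq_frac, power_values=values)


def azimuthal_tail(image, freq_frac: float, n_bins: int = 64) -> SpectrumTail:
    """1-D azimuthally averaged spectrum tail (cross-check variant).

    The power spectrum is averaged over rings of normalized radius up to 1,
    and the top ``freq_frac`` of ring averages form the tail values.
    """
    x = _as_array(image)
    x = x - x.mean()
    power = np.abs(np.fft.fft2(x)) ** 2
    r = radial_frequency_grid(x.shape)
    sel = (r > 0) & (r <= 1.0)
    bins = np.minimum((r[sel] * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(bins, weights=power[sel], minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    profile = sums[counts > 0] / counts[counts > 0]
    k = max(1, int(round(freq_frac * profile.size)))
    return SpectrumTail(freq_frac=freq_frac, power_values=profile[-k:])


def tail_statistics(tail: SpectrumTail) -> TailStats:
    """The seven descriptive statistics of a spectrum tail."""
    v = np.asarray(tail.power_values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty tail")
    mean = float(v.mean())
    m2 = float(((v - mean) ** 2).mean())
    std = math.sqrt(m2)
    if m2 == 0.0:
        kurtosis = float("nan")
        skewness = float("nan")
    else:
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        kurtosis = m4 / m2**2
        skewness = m3 / m2**1.5
    return TailStats(
        mean=mean,
        inverse_mean=1.0 / mean if mean > 0 else float("inf"),
        std=std,
        inverse_std=1.0 / std if std > 0 else float("inf"),
        coefficient_of_variation=std / mean if mean > 0 else float("nan"),
        kurtosis=kurtosis,
        skewness=skewness,
    )


def image_tail_kurtosis(image, freq_frac: float,
                        log_power: bool = False) -> float:
    """Convenience: tail kurtosis of one image."""
    return tail_statistics(
        power_spectrum_tail(image, freq_frac, log_power=log_power)
    ).kurtosis


def apply_quality_condition(images: Sequence, condition: QualityCondition,
                            image_ids: Optional[Sequence] = None,
                            exclude_nan: bool = True) -> QualityReport:
    """Flag images whose tail kurtosis exceeds the condition's cutoff.

    The null condition excludes nothing. Images whose kurtosis is the NaN
    sentinel (zero-variance tail) are excluded by default, configurable via
    ``exclude_nan``.
    """
    if image_ids is None:
        image_ids = list(range(len(images)))
    rows = []
    for img_id, image in zip(image_ids, images):
        if condition.is_null:
            kurt = float("nan")
            excluded = False
        else:
            kurt = image_tail_kurtosis(image, condition.freq_frac)
            if math.isnan(kurt):
                excluded = bool(exclude_nan)
            else:
                excluded = kurt > condition.kurtosis_cutoff
        rows.append({"image_id": img_id, "kurtosis": kurt,
                     "excluded": excluded})
    return QualityReport(condition=condition, table=pd.DataFrame(rows))


def stack_kurtosis_profile(zstack: ZStack, freq_frac: float = 0.2,
                           normalize_to: Optional[float] = None
                           ) -> np.ndarray:
    """Per-slice tail kurtosis in depth order, optionally normalized.

    ``normalize_to`` divides the profile by a reference maximum (e.g. the
    kurtosis maximum over a whole subset of stacks), a pure visualization
    aid; exclusion decisions always use absolute kurtosis.
    """
    if len(zstack) < 2:
        raise ValueError("need a stack with at least 2 slices")
    profile = np.array([
        image_tail_kurtosis(s, freq_frac) for s in zstack.slices
    ])
    if normalize_to is not None:
        if normalize_to <= 0:
            raise ValueError("normalize_to must be > 0")
        profile = profile / normalize_to
    return profile


def condition_sweep(images: Sequence,
                    conditions: Iterable = DEFAULT_CONDITIONS,
                    image_ids: Optional[Sequence] = None
                    ) -> list[QualityReport]:
    """One QualityReport per condition over the same image set."""
    images = list(images)
    if not images:
        raise ValueError("empty image set")
    reports = []
    for cond in conditions:
        if not isinstance(cond, QualityCondition):
            cond = QualityCondition(*cond)
        reports.append(
            apply_quality_condition(images, cond, image_ids=image_ids)
        )
    return reports


def sweep_summary(reports: Sequence[QualityReport]) -> pd.DataFrame:
    """Tabulate a sweep: one row per condition with exclusion counts."""
    rows = []
    for i, rep in enumerate(reports, start=1):
        rows.append({
            "condition": i,
            "freq_frac": rep.condition.freq_frac,
            "kurtosis_cutoff": rep.condition.kurtosis_cutoff,
            "n_images": rep.n_images,
            "n_excluded": rep.n_excluded,
            "fraction_excluded": rep.fraction_excluded,
        })
    return pd.DataFrame(rows)
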