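"""Spectrum-tail statistics and the kurtosis exclusion rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thgqc.io_manifest import ImageRecord
from thgqc.quality import (
    DEFAULT_CONDITIONS,
    QualityCondition,
    SpectrumTail,
    apply_quality_condition,
    azimuthal_tail,
    condition_sweep,
    image_tail_kurtosis,
    power_spectrum_tail,
    radial_frequency_grid,
    stack_kurtosis_profile,
    sweep_summary,
    tail_statistics,
)
from thgqc.phantoms import PhantomParams, render_zstack


def brute_force_stats(values):
    """Direct standardized-moment arithmetic (the oracle)."""
    v = [float(x) for x in values]
    n = len(v)
    mean = sum(v) / n
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    kurt = m4 / m2**2 if m2 else float("nan")
    skew = m3 / m2**1.5 if m2 else float("nan")
    return mean, math.sqrt(m2), kurt, skew


class TestSpectrumTail:
    def test_constant_image_all_tail_power_zero(self):
        tail = power_spectrum_tail(np.full((32, 32), 7.0), 0.2)
        assert (tail.power_values == 0).all()
        assert math.isnan(tail_statistics(tail).kurtosis)

    def test_low_frequency_sinusoid_excluded_from_tail(self):
        y = np.arange(64)
        img = np.sin(2 * np.pi * y / 32.0)[:, None] * np.ones((1, 64))
        tail = power_spectrum_tail(img, 0.2)
        full_power = np.abs(np.fft.fft2(img - img.mean())) ** 2
        assert tail.power_values.max() < 1e-12 * full_power.max()

    def test_tail_count_matches_radial_grid_enumeration(self, rng):
        img = rng.normal(size=(40, 56))
        tail = power_spectrum_tail(img, 0.2)
        r = radial_frequency_grid((40, 56))
        expected = int((r >= 0.8).sum())  # DC has r=0, never in the tail
        assert tail.power_values.size == expected

    def test_bad_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            power_spectrum_tail(rng.normal(size=(8, 8)), 0.2)
        img = rng.normal(size=(32, 32))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            power_spectrum_tail(img, 0.2)
        with pytest.raises(ValueError):
            power_spectrum_tail(rng.normal(size=(32, 32)), 0.0)


class TestTailStatistics:
    def test_zero_variance_sentinel(self):
        stats = tail_statistics(SpectrumTail(0.2, np.ones(4)))
        assert stats.mean == 1.0 and stats.std == 0.0
        assert math.isnan(stats.kurtosis) and math.isnan(stats.skewness)

    def test_five_point_fixture_matches_brute_force(self):
        values = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        stats = tail_statistics(SpectrumTail(0.2, values))
        mean, std, kurt, skew = brute_force_stats(values)
        assert stats.mean == pytest.approx(mean)
        assert stats.std == pytest.approx(std)
        assert stats.kurtosis == pytest.approx(kurt, rel=1e-12)
        assert stats.skewness == pytest.approx(skew, rel=1e-12)
        assert stats.inverse_mean == pytest.approx(1 / mean)
        assert stats.coefficient_of_variation == pytest.approx(std / mean)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=3,
                    max_size=200))
    def test_statistics_match_brute_force_oracle(self, values):
        arr = np.array(values)
        stats = tail_statistics(SpectrumTail(0.5, arr))
        mean, std, kurt, skew = brute_force_stats(arr)
        assert stats.mean == pytest.approx(mean, rel=1e-10, abs=1e-12)
        if std > 1e-9 * (abs(mean) + 1):
            assert stats.kurtosis == pytest.approx(kurt, rel=1e-8)
            assert stats.skewness == pytest.approx(skew, rel=1e-8)

    def test_gaussian_sample_kurtosis_is_three(self):
        rng = np.random.default_rng(0)
        stats = tail_statistics(SpectrumTail(0.2, rng.normal(size=10**6)))
        assert stats.kurtosis == pytest.approx(3.0, abs=0.05)


class TestInvariances:
    def test_rotation_invariance_exact(self, rng):
        img = rng.normal(size=(48, 48))
        k1 = image_tail_kurtosis(img, 0.2)
        k2 = image_tail_kurtosis(np.rot90(img), 0.2)
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_intensity_scale_invariance(self, rng):
        img = rng.normal(size=(48, 48)) + 10
        k1 = image_tail_kurtosis(img, 0.3)
        k2 = image_tail_kurtosis(3.7 * img, 0.3)
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_azimuthal_mode_agrees_on_white_noise_scale(self, rng):
        # ring averages of white noise are flat: low kurtosis, finite
        img = rng.normal(size=(64, 64))
        tail = azimuthal_tail(img, 0.2)
        assert tail.power_values.size > 3
        assert np.isfinite(tail_statistics(tail).kurtosis)


class TestExclusionRule:
    def _images(self, rng):
        # white-noise images with incrementally heavier high-frequency
        # outliers -> strictly increasing tail kurtosis
        imgs = []
        for boost in (0.0, 4.0, 9.0):
            img = rng.normal(size=(48, 48))
            img += boost * np.cos(2 * np.pi * 0.45 * np.arange(48))[None, :]
            imgs.append(img)
        return imgs

    def test_null_condition_excludes_nothing(self, rng):
        report = apply_quality_condition(self._images(rng),
                                         QualityCondition())
        assert report.n_excluded == 0

    def test_threshold_monotonicity_is_superset(self, rng):
        imgs = self._images(rng)
        strict = apply_quality_condition(imgs, QualityCondition(0.2, 5.0))
        loose = apply_quality_condition(imgs, QualityCondition(0.2, 10.0))
        assert loose.excluded_ids <= strict.excluded_ids

    def test_exclusion_matches_direct_comparison(self, rng):
        imgs = self._images(rng)
        cutoff = 10.0
        report = apply_quality_condition(imgs, QualityCondition(0.2, cutoff))
        for _, row in report.table.iterrows():
            assert row["excluded"] == (row["kurtosis"] > cutoff)

    def test_half_set_condition_rejected(self):
        with pytest.raises(ValueError):
            QualityCondition(freq_frac=0.2, kurtosis_cutoff=None)

    def test_sweep_default_has_seven_rows(self, rng):
        reports = condition_sweep(self._images(rng))
        assert len(reports) == len(DEFAULT_CONDITIONS) == 7
        table = sweep_summary(reports)
        assert table.loc[0, "n_excluded"] == 0  # the null condition row
        # for fixed freq_frac, cutoff 5 excludes at least as many as 10
        by = {(r.condition.freq_frac, r.condition.kurtosis_cutoff):
              r.n_excluded for r in reports[1:]}
        for freq in (0.4, 0.2, 0.1):
            assert by[(freq, 5.0)] >= by[(freq, 10.0)]

    def test_empty_image_set_rejected(self):
        with pytest.raises(ValueError):
            condition_sweep([])


class TestStackProfile:
    def _stack(self, decay, seed=0):
        params = PhantomParams(
            height=96, width=96, cell_radius_um=(1.5, 3.0),
            cell_density_normal_per_mm2=1300.0,
            cell_density_tumor_per_mm2=5200.0, fiber_count=2,
            depth_decay_per_um=decay, depth_step_um=10.0,
        )
        return render_zstack(params, "tumor", 4,
                             np.random.default_rng(seed))

    def test_identical_slices_give_constant_profile(self):
        base = np.random.default_rng(0).normal(size=(32, 32))
        pixels = np.clip(base * 1000 + 30000, 0, 65535).astype(np.uint16)
        from thgqc.io_manifest import ZStack
        slices = [ImageRecord(pixels, 0.5, case_id="c", depth_index=k)
                  for k in range(3)]
        profile = stack_kurtosis_profile(ZStack(slices), 0.2)
        assert np.ptp(profile) == 0.0

    def test_normalization_bounds_and_validation(self):
        stack = self._stack(0.05)
        profile = stack_kurtosis_profile(stack, 0.2)
        normalized = stack_kurtosis_profile(stack, 0.2,
                                            normalize_to=profile.max())
        assert normalized.max() == pytest.approx(1.0)
        assert (normalized <= 1.0 + 1e-12).all()
        with pytest.raises(ValueError):
            stack_kurtosis_profile(stack, 0.2, normalize_to=0.0)
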