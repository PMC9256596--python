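"""Sliding-window score maps: coverage, conservation, binarization, IOU."""

import numpy as np
import pytest

from thgqc.io_manifest import MASK_BACKGROUND, MASK_NORMAL, MASK_TUMOR, Mosaic
from thgqc.overlay import (
    ScoreMap,
    binarize_overlay,
    jaccard_per_class,
    sliding_window_scores,
    window_positions,
)


class ConstantModel:
    """Duck-typed stand-in scoring every window with a fixed value."""

    class config:
        min_input_side = 2

    def __init__(self, score=0.5):
        self.logit = np.log(score / (1 - score))

    def forward_logits(self, batch, train=False):
        return np.full(batch.shape[0], self.logit)


class MeanModel(ConstantModel):
    """Score = mean window intensity (monotone content probe)."""

    def forward_logits(self, batch, train=False):
        m = batch.reshape(batch.shape[0], -1).mean(axis=1)
        return np.log(np.clip(m, 1e-6, 1 - 1e-6) / (1 - np.clip(m, 1e-6, 1 - 1e-6)))


def _mosaic(pixels):
    return Mosaic(np.asarray(pixels), pixel_size_um=0.5)


class TestSlidingWindow:
    def test_constant_model_constant_map(self, rng):
        mosaic = _mosaic(rng.random((12, 16)).astype(np.float32))
        smap = sliding_window_scores(mosaic, ConstantModel(0.7),
                                     window_size=4, stride=2)
        covered = smap.covered
        np.testing.assert_allclose(smap.mean_score[covered], 0.7, atol=1e-9)

    def test_4x4_mosaic_2x2_window_coverage_pattern(self):
        mosaic = _mosaic(np.zeros((4, 4), np.float32))
        smap = sliding_window_scores(mosaic, ConstantModel(), window_size=2,
                                     stride=1)
        assert len(window_positions((4, 4), 2, 1)) == 9
        expect = np.array([[1, 2, 2, 1],
                           [2, 4, 4, 2],
                           [2, 4, 4, 2],
                           [1, 2, 2, 1]])
        np.testing.assert_array_equal(smap.coverage_count, expect)

    @pytest.mark.parametrize("shape,window,stride", [
        ((16, 16), 4, 1), ((20, 24), 5, 3), ((9, 13), 4, 4), ((64, 64), 8, 5),
    ])
    def test_coverage_matches_brute_force_enumeration(self, shape, window,
                                                      stride):
        mosaic = _mosaic(np.zeros(shape, np.float32))
        smap = sliding_window_scores(mosaic, ConstantModel(),
                                     window_size=window, stride=stride)
        brute = np.zeros(shape, dtype=int)
        for i in range(0, shape[0] - window + 1, stride):
            for j in range(0, shape[1] - window + 1, stride):
                brute[i:i + window, j:j + window] += 1
        np.testing.assert_array_equal(smap.coverage_count, brute)

    def test_score_mass_conservation_identity(self, rng):
        mosaic = _mosaic(rng.random((24, 32)).astype(np.float32))
        window, stride = 6, 3

        class Recording(MeanModel):
            logits: list = []

            def forward_logits(self, batch, train=False):
                z = super().forward_logits(batch, train)
                self.logits.extend(z.tolist())
                return z

        model = Recording()
        smap = sliding_window_scores(mosaic, model, window_size=window,
                                     stride=stride)
        covered = smap.covered
        lhs = np.sum(smap.mean_score[covered] * smap.coverage_count[covered])
        scores = 1.0 / (1.0 + np.exp(-np.array(model.logits, dtype=np.float64)))
        assert len(scores) == len(window_positions((24, 32), window, stride))
        assert lhs == pytest.approx(scores.sum() * window * window, abs=1e-9)

    def test_coarser_stride_never_increases_coverage(self, rng):
        mosaic = _mosaic(rng.random((16, 16)).astype(np.float32))
        s1 = sliding_window_scores(mosaic, ConstantModel(), 4, 1)
        s2 = sliding_window_scores(mosaic, ConstantModel(), 4, 2)
        assert (s2.coverage_count <= s1.coverage_count).all()

    def test_gap_stride_warns_and_marks_undefined(self):
        mosaic = _mosaic(np.zeros((10, 10), np.float32))
        with pytest.warns(UserWarning, match="gaps"):
            smap = sliding_window_scores(mosaic, ConstantModel(), 3, 5)
        assert (smap.coverage_count == 0).any()
        assert np.isnan(smap.mean_score[smap.coverage_count == 0]).all()

    def test_undersized_mosaic_rejected(self):
        with pytest.raises(ValueError, match="smaller than window"):
            sliding_window_scores(_mosaic(np.zeros((8, 8), np.float32)),
                                  ConstantModel(), 16, 1)


class TestBinarize:
    def _map(self, values, coverage=None):
        values = np.asarray(values, float)
        if coverage is None:
            coverage = np.ones_like(values, dtype=int)
        return ScoreMap(values, np.asarray(coverage), 2, 1)

    def test_uniform_high_scores_all_tumor(self):
        mask = binarize_overlay(self._map(np.full((4, 4), 0.9)), 0.5)
        assert (mask == MASK_TUMOR).all()

    def test_threshold_one_with_lower_scores_all_normal(self):
        mask = binarize_overlay(self._map(np.full((4, 4), 0.99)), 1.0)
        assert (mask == MASK_NORMAL).all()

    def test_ramp_splits_at_midpoint_and_uncovered_is_background(self):
        values = np.tile(np.linspace(0, 1, 10), (4, 1))
        coverage = np.ones((4, 10), int)
        coverage[:, 0] = 0
        values[:, 0] = np.nan
        mask = binarize_overlay(self._map(values, coverage), 0.5)
        assert (mask[:, 0] == MASK_BACKGROUND).all()
        direct = np.where(values >= 0.5, MASK_TUMOR, MASK_NORMAL)
        np.testing.assert_array_equal(mask[:, 1:], direct[:, 1:])


class TestJaccard:
    def test_identity_masks(self):
        mask = np.array([[1, 1, 2], [2, 2, 1]])
        iou = jaccard_per_class(mask, mask)
        assert iou.iou_normal == 1.0 and iou.iou_tumor == 1.0

    def test_disjoint_assignments(self):
        pred = np.full((3, 3), MASK_TUMOR)
        ref = np.full((3, 3), MASK_NORMAL)
        iou = jaccard_per_class(pred, ref)
        assert iou.iou_normal == 0.0 and iou.iou_tumor == 0.0

    def test_row_overlap_fixture(self):
        pred = np.full((4, 4), MASK_NORMAL)
        ref = np.full((4, 4), MASK_NORMAL)
        pred[0:2] = MASK_TUMOR
        ref[1:3] = MASK_TUMOR
        iou = jaccard_per_class(pred, ref)
        assert iou.iou_tumor == pytest.approx(1 / 3)

    def test_absent_class_yields_nan_sentinel(self):
        pred = np.full((2, 2), MASK_NORMAL)
        ref = np.full((2, 2), MASK_NORMAL)
        iou = jaccard_per_class(pred, ref)
        assert np.isnan(iou.iou_tumor) and iou.iou_normal == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            jaccard_per_class(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBoundaryRecovery:
    def test_trained_model_recovers_tumor_boundary(self, separable_run):
        """A model trained on separable phantoms segments a density-ramp
        mosaic with high tumor IOU against the generator's reference mask;
        the overlay threshold is the model's own Youden operating point."""
        from thgqc.evaluation import ScoredSet, roc_auc, youden_threshold
        from thgqc.experiments import boundary_mosaic

        model, _, val_samples = separable_run
        scores = model.predict_scores([s.pixels for s in val_samples])
        scored = ScoredSet(scores=scores,
                           labels=np.array([s.label for s in val_samples]))
        threshold = youden_threshold(roc_auc(scored))
        mosaic = boundary_mosaic(seed=21)
        smap = sliding_window_scores(mosaic, model, window_size=96, stride=16)
        pred = binarize_overlay(smap, threshold)
        covered = smap.covered
        ref = np.where(covered, mosaic.reference_mask, MASK_BACKGROUND)
        iou = jaccard_per_class(pred, ref)
        assert iou.iou_tumor >= 0.7
        assert iou.iou_normal >= 0.7
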