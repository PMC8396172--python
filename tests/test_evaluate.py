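"""Detection post-processing, hit matching, metrics, and curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from murilung.core import BinaryMask, CTVolume
from murilung.evaluate import (
    ConfusionCounts,
    detection_dice,
    label_components,
    labeled_tumors,
    match_detections,
    postprocess,
    precision,
    recall,
    roc_like_curve,
    size_binned_rates,
    threshold_sweep,
)

SP = 300.0  # um; voxel volume 0.027 mm^3


def _map(shape=(16, 32, 32)):
    return np.zeros(shape, dtype=np.float32)


def _full_lung(shape=(16, 32, 32)):
    return BinaryMask(np.ones(shape, dtype=np.uint8), SP)


def _ct(arr):
    return CTVolume(arr, SP)


class TestPostprocess:
    def test_minimum_volume_filter(self):
        """A 0.11 mm^3 component is rejected, a 0.22 mm^3 one kept."""
        p = _map()
        p[2, 2:6, 2] = 0.9  # 4 voxels = 0.108 mm^3
        p[8, 8:10, 8:12] = 0.9  # 8 voxels = 0.216 mm^3
        dets = postprocess(_ct(p), _full_lung(), 0.5)
        assert len(dets) == 1
        assert dets[0].volume_mm3 == pytest.approx(8 * 0.027)

    def test_outside_lung_rejected(self):
        p = _map()
        p[2:5, 2:5, 2:5] = 0.9
        lung = BinaryMask(np.zeros((16, 32, 32), dtype=np.uint8), SP)
        lung.voxels[10:, :, :] = 1
        assert postprocess(_ct(p), lung, 0.5) == []

    def test_zero_threshold_spans_mask(self):
        p = np.full((8, 8, 8), 0.2, dtype=np.float32)
        lung = BinaryMask(np.ones((8, 8, 8), dtype=np.uint8), SP)
        dets = postprocess(CTVolume(p, SP), lung, 0.0)
        assert len(dets) == 1
        assert len(dets[0].voxels) == 8**3

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            postprocess(_ct(_map()), _full_lung(), 1.5)


def _det_from(p, thr=0.5):
    return label_components(p > thr, _ct(p))


class TestMatching:
    def _one_label(self):
        lab = np.zeros((16, 32, 32), dtype=np.uint8)
        lab[6:10, 6:10, 6:10] = 1  # 64 voxels, r_eq = (3V/4pi)^(1/3)
        return BinaryMask(lab, SP)

    def test_direct_hit(self):
        labels = self._one_label()
        p = _map()
        p[7:9, 7:9, 7:9] = 0.9
        c = match_detections(_det_from(p), labels)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_near_hit_inside_radius(self):
        """Detection centroid at 1.4 equivalent radii: a near hit."""
        labels = self._one_label()
        tumor = labeled_tumors(labels)[0]
        r = tumor.equivalent_radius_mm
        offset_vox = int(np.floor(1.4 * r / (SP / 1000)))
        p = _map()
        z = 8 + offset_vox
        p[z, 7:9, 7:9] = 0.9  # small detection offset along z, no overlap
        dets = _det_from(p)
        d = np.linalg.norm(dets[0].centroid_mm - tumor.centroid_mm)
        assert d <= 1.5 * r  # construction sanity
        c = match_detections(dets, labels)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_far_detection_is_fp_plus_fn(self):
        labels = self._one_label()
        tumor = labeled_tumors(labels)[0]
        r = tumor.equivalent_radius_mm
        offset_vox = int(np.ceil(2.0 * r / (SP / 1000))) + 2
        p = _map()
        p[8, 7:9, (7 + offset_vox) : (9 + offset_vox)] = 0.9
        dets = _det_from(p)
        d = np.linalg.norm(dets[0].centroid_mm - tumor.centroid_mm)
        assert d > 1.5 * r
        c = match_detections(dets, labels)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_two_detections_one_label_single_tp(self):
        """A tumor split into two detections: still one TP and no FP."""
        labels = self._one_label()
        p = _map()
        p[6:8, 6:8, 6:8] = 0.9
        p[9, 9, 9] = 0.9  # disjoint second detection inside the label
        dets = _det_from(p)
        assert len(dets) == 2
        c = match_detections(dets, labels)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_one_detection_two_labels_credits_both(self):
        lab = np.zeros((16, 32, 32), dtype=np.uint8)
        lab[6:8, 6:8, 6:8] = 1
        lab[6:8, 6:8, 12:14] = 1
        labels = BinaryMask(lab, SP)
        p = _map()
        p[6:8, 6:8, 6:14] = 0.9  # one detection spanning both labels
        c = match_detections(_det_from(p), labels)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_invariant_to_voxel_order(self):
        labels = self._one_label()
        p = _map()
        p[7:9, 7:9, 7:9] = 0.9
        dets = _det_from(p)
        for d in dets:
            d.voxels = d.voxels[::-1].copy()
        c = match_detections(dets, labels)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)


class TestRates:
    @pytest.mark.parametrize(
        "tp,fp,fn,p_exp,r_exp,d_exp",
        [
            (138, 84, 69, 0.622, 0.667, 0.643),
            (148, 120, 59, 0.552, 0.715, 0.623),
            (147, 91, 60, 0.618, 0.710, 0.661),
            (139, 72, 68, 0.659, 0.671, 0.665),
        ],
    )
    def test_published_count_arithmetic(self, tp, fp, fn, p_exp, r_exp, d_exp):
        """Precision/recall/Dice reproduce the study's printed three-decimal
        values from its raw counts."""
        c = ConfusionCounts(tp, fp, fn)
        assert round(precision(c), 3) == p_exp
        assert round(recall(c), 3) == r_exp
        assert round(detection_dice(c), 3) == d_exp

    def test_degenerate_counts(self):
        assert precision(ConfusionCounts(0, 0, 5)) == 0.0
        assert recall(ConfusionCounts(0, 3, 0)) == 0.0
        assert detection_dice(ConfusionCounts(5, 0, 0)) == 1.0
        with pytest.raises(ValueError):
            detection_dice(ConfusionCounts(0, 0, 0))
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=50, deadline=None)
    def test_dice_is_harmonic_mean(self, tp, fp, fn):
        if tp == 0 or (2 * tp + fp + fn) == 0:
            return
        c = ConfusionCounts(tp, fp, fn)
        p, r = precision(c), recall(c)
        assert detection_dice(c) == pytest.approx(2 * p * r / (p + r))

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=50, deadline=None)
    def test_rates_in_unit_interval(self, tp, fp, fn):
        c = ConfusionCounts(tp, fp, fn)
        assert 0.0 <= precision(c) <= 1.0
        assert 0.0 <= recall(c) <= 1.0


class TestSweep:
    def _scene(self, seed=0, n_fp=2):
        from murilung.phantom import generate_prediction_map

        lab = np.zeros((20, 40, 40), dtype=np.uint8)
        lab[6:10, 8:12, 8:12] = 1
        lab[6:10, 26:30, 26:30] = 1
        labels = BinaryMask(lab, SP)
        lung = BinaryMask(np.ones_like(lab), SP)
        lung.voxels[:2] = 0
        pm = generate_prediction_map(
            labels, np.random.default_rng(seed), n_false_pos=n_fp,
            lung_mask=lung, score_range=(0.55, 0.95),
        )
        return pm, labels, lung

    def test_grid_has_101_points(self):
        pm, labels, lung = self._scene()
        pts, _ = threshold_sweep([pm], [labels], [lung])
        assert len(pts) == 101

    def test_symmetric_crossing_interpolates_to_half(self):
        """On synthetic curves P(t) = t and R(t) = 1 - t the optimum is 0.5."""
        thresholds = np.arange(0.0, 1.0001, 0.1)
        diff = thresholds - (1 - thresholds)
        i = int(np.where(np.diff(np.signbit(diff)))[0][0])
        frac = -diff[i] / (diff[i + 1] - diff[i])
        assert thresholds[i] + frac * 0.1 == pytest.approx(0.5)

    def test_monotone_counts_over_threshold(self):
        """Raising the threshold never increases TP or FP."""
        pm, labels, lung = self._scene(seed=3, n_fp=3)
        pts, _ = threshold_sweep([pm], [labels], [lung], np.arange(0.0, 1.01, 0.05))
        tps = [p.counts.tp for p in pts]
        fps = [p.counts.fp for p in pts]
        assert all(a >= b for a, b in zip(tps, tps[1:]))
        assert all(a >= b for a, b in zip(fps, fps[1:]))

    def test_empty_predictions_warn_and_fall_back(self):
        lab = np.zeros((8, 8, 8), dtype=np.uint8)
        lab[3:5, 3:5, 3:5] = 1
        labels = BinaryMask(lab, SP)
        lung = BinaryMask(np.ones_like(lab), SP)
        pm = CTVolume(np.zeros((8, 8, 8), dtype=np.float32), SP)
        with pytest.warns(UserWarning):
            _, t = threshold_sweep([pm], [labels], [lung], np.array([0.2, 0.5, 0.8]))
        assert t in (0.2, 0.5, 0.8)


class TestROC:
    def test_perfect_detector_auc_one(self):
        from murilung.phantom import generate_prediction_map

        lab = np.zeros((16, 32, 32), dtype=np.uint8)
        lab[6:10, 8:12, 8:12] = 1
        labels = BinaryMask(lab, SP)
        lung = BinaryMask(np.ones_like(lab), SP)
        pm = generate_prediction_map(labels, np.random.default_rng(0), lung_mask=lung)
        _, auc = roc_like_curve([pm], [labels], [lung])
        assert auc == pytest.approx(1.0)

    def test_label_blind_detector_auc_near_half(self):
        """Prediction blobs placed independently of the labels: AUC ~ 0.5
        averaged over seeded random maps."""
        shape = (20, 32, 32)
        lab = np.zeros(shape, dtype=np.uint8)
        lab[7:13, 13:19, 13:19] = 1
        labels = BinaryMask(lab, SP)
        lung = BinaryMask(np.ones(shape, dtype=np.uint8), SP)
        aucs = []
        # blob count chosen so chance hits and false positives are comparable
        for seed in range(30):
            rng = np.random.default_rng(seed)
            p = np.zeros(shape, dtype=np.float32)
            for _ in range(20):
                z, y, x = rng.integers(1, 17), rng.integers(1, 29), rng.integers(1, 29)
                p[z : z + 2, y : y + 2, x : x + 2] = np.maximum(
                    p[z : z + 2, y : y + 2, x : x + 2], rng.uniform(0.05, 0.95)
                )
            aucs.append(roc_like_curve([CTVolume(p, SP)], [labels], [lung],
                                       np.arange(0.0, 1.0, 0.05))[1])
        assert 0.3 < float(np.mean(aucs)) < 0.7

    def test_single_threshold_trapezoid(self):
        pm = CTVolume(np.zeros((8, 8, 8), dtype=np.float32), SP)
        lab = np.zeros((8, 8, 8), dtype=np.uint8)
        lab[3:5, 3:5, 3:5] = 1
        curve, auc = roc_like_curve(
            [pm], [BinaryMask(lab, SP)], [BinaryMask(np.ones_like(lab), SP)],
            np.array([0.5]),
        )
        assert len(curve) == 1
        assert auc == pytest.approx(0.0)  # no detections anywhere


class TestSizeBins:
    def _labels_of_sizes(self, n_vox_list):
        lab = np.zeros((20, 60, 60), dtype=np.uint8)
        x = 4
        for n in n_vox_list:
            side = int(np.ceil(n ** (1 / 3)))
            count = 0
            for z in range(side):
                for y in range(side):
                    for xx in range(side):
                        if count < n:
                            lab[6 + z, 6 + y, x + xx] = 1
                            count += 1
            x += side + 6
        return BinaryMask(lab, SP)

    def test_all_detected_every_bin_full(self):
        labels = self._labels_of_sizes([8, 27, 64])
        p = np.zeros((20, 60, 60), dtype=np.float32)
        p[labels.as_bool()] = 0.9
        dets = label_components(p > 0.5, CTVolume(p, SP))
        rates = size_binned_rates(labels, dets)
        finite = [r for r in rates if not np.isnan(r)]
        assert finite and all(r == 1.0 for r in finite)

    def test_single_two_mm3_label(self):
        labels = self._labels_of_sizes([74])  # 74 voxels ~ 2.0 mm^3
        p = np.zeros((20, 60, 60), dtype=np.float32)
        p[labels.as_bool()] = 0.9
        dets = label_components(p > 0.5, CTVolume(p, SP))
        rates = size_binned_rates(labels, dets)
        assert rates[4 - 1] == 1.0  # [1, 5) bin
        assert all(np.isnan(r) for i, r in enumerate(rates) if i != 3)

    def test_quarter_detection_in_smallest_bin(self):
        labels = self._labels_of_sizes([6, 6, 6, 6])  # 0.162 mm^3 each
        tumors = labeled_tumors(labels)
        p = np.zeros((20, 60, 60), dtype=np.float32)
        p[tuple(tumors[0].voxels.T)] = 0.9
        dets = label_components(p > 0.5, CTVolume(p, SP))
        rates = size_binned_rates(labels, dets)
        assert rates[0] == pytest.approx(0.25)

    def test_unordered_bins_rejected(self):
        with pytest.raises(ValueError):
            size_binned_rates(self._labels_of_sizes([8]), [], (1.0, 0.5))
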