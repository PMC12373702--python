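"""Fluid quantification, EER calibration, grader agreement, stand-in segmenter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octneed import biomarkers as bm
from octneed.cohort import FluidState
from octneed.preprocess import LayerSet, OCTVolume
from octneed.render import render_scan


def _mask(labels, spacings=(120.0, 10.0, 10.0)):
    return bm.SegmentationMask(np.asarray(labels, dtype=np.uint8), spacings)


class TestFluidVolume:
    def test_500_voxels_at_12000_um3_is_6nl(self):
        labels = np.zeros((5, 10, 10), dtype=np.uint8)
        labels.ravel()[:500] = bm.IRF_LABEL
        m = _mask(labels, (120.0, 10.0, 10.0))
        assert bm.fluid_volume_nl(m, "irf") == pytest.approx(6.0, rel=1e-12)

    def test_empty_mask_zero(self):
        assert bm.fluid_volume_nl(_mask(np.zeros((2, 2, 2))), bm.SRF_LABEL) == 0.0

    def test_additive_over_disjoint_components(self):
        rng = np.random.default_rng(0)
        a = np.zeros((4, 8, 8), dtype=np.uint8)
        b = np.zeros_like(a)
        a[rng.random(a.shape) < 0.2] = bm.IRF_LABEL
        b[(rng.random(a.shape) < 0.2) & (a == 0)] = bm.IRF_LABEL
        v_union = bm.fluid_volume_nl(_mask(a | b), bm.IRF_LABEL)
        assert v_union == pytest.approx(
            bm.fluid_volume_nl(_mask(a), 1) + bm.fluid_volume_nl(_mask(b), 1), rel=1e-12)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            bm.fluid_volume_nl(_mask(np.zeros((2, 2, 2))), "ped")


class TestSRFHeight:
    def test_no_srf_is_zero(self):
        assert bm.srf_max_height_um(_mask(np.zeros((2, 4, 4)))) == 0.0

    def test_13_contiguous_voxels_at_3p9um(self):
        labels = np.zeros((1, 30, 4), dtype=np.uint8)
        labels[0, 5:18, 2] = bm.SRF_LABEL
        m = _mask(labels, (120.0, 3.9, 10.0))
        h = bm.srf_max_height_um(m)
        assert h == pytest.approx(13 * 3.9)
        assert h >= 50.0

    def test_disjoint_runs_not_summed(self):
        labels = np.zeros((1, 30, 3), dtype=np.uint8)
        labels[0, 2:7, 1] = bm.SRF_LABEL     # run of 5
        labels[0, 10:15, 1] = bm.SRF_LABEL   # separate run of 5
        m = _mask(labels, (120.0, 4.0, 10.0))
        assert bm.srf_max_height_um(m) == pytest.approx(5 * 4.0)


class TestEERThreshold:
    def test_separable_classes_midpoint(self):
        vals = [0.2, 0.5, 0.9, 2.5, 3.0, 4.0]
        ref = [False, False, False, True, True, True]
        t = bm.calibrate_eer_threshold(vals, ref)
        assert 0.9 < t < 2.5
        pred = np.asarray(vals) >= t
        assert np.array_equal(pred, ref)

    def test_four_point_example(self):
        assert bm.calibrate_eer_threshold([0, 1, 2, 3], [False, False, True, True]) == 1.5

    def test_label_swap_swaps_error_rates(self):
        rng = np.random.default_rng(1)
        vals = rng.random(40)
        ref = rng.random(40) < 0.5
        for t in np.linspace(0.1, 0.9, 9):
            pred = vals >= t
            fpr = (pred & ~ref).sum() / (~ref).sum()
            fnr = (~pred & ref).sum() / ref.sum()
            pred_sw = ~pred  # swapping labels and flipping the test direction
            fpr_sw = (pred_sw & ref).sum() / ref.sum()
            fnr_sw = (~pred_sw & ~ref).sum() / (~ref).sum()
            assert fpr == pytest.approx(fnr_sw) and fnr == pytest.approx(fpr_sw)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=60),
           st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_bruteforce(self, vals, lab_seed):
        rng = np.random.default_rng(lab_seed)
        ref = rng.random(len(vals)) < 0.5
        if ref.all() or (~ref).all() or len(np.unique(vals)) < 2:
            return
        t = bm.calibrate_eer_threshold(vals, ref)
        uniq = np.unique(vals)
        cands = (uniq[:-1] + uniq[1:]) / 2

        def gap(th):
            pred = np.asarray(vals) >= th
            return abs((pred & ~ref).sum() / (~ref).sum()
                       - ((~pred) & ref).sum() / ref.sum())

        best = min(gap(c) for c in cands)
        assert gap(t) == pytest.approx(best, abs=1e-12)
        # tie-break toward the lower threshold
        assert all(gap(c) > best - 1e-12 for c in cands if c < t)
        assert not any(abs(gap(c) - best) < 1e-12 and c < t for c in cands)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bm.calibrate_eer_threshold([1, 2, 3], [True, True, True])


class TestPresenceFlags:
    def test_boundary_inclusive_at_6nl(self):
        m = bm.FluidMetrics(6.0, 0.0, 0.0)
        assert bm.presence_flags(m).irf_present is np.True_ or bm.presence_flags(m).irf_present

    def test_just_below_threshold_absent(self):
        assert not bm.presence_flags(bm.FluidMetrics(5.9, 0.0, 0.0)).irf_present

    def test_zero_srf_all_flags_false(self):
        f = bm.presence_flags(bm.FluidMetrics(0.0, 0.0, 0.0))
        assert not f.srf_present and not f.srf_ge_50um

    def test_srf_50um_flag(self):
        f = bm.presence_flags(bm.FluidMetrics(0.0, 30.0, 50.0))
        assert f.srf_ge_50um

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            bm.presence_flags(bm.FluidMetrics(1, 1, 1), {"irf": -1.0})


class TestAgreement:
    def test_identical_raters_perfect(self):
        flags = np.array([True, False, True, True, False])
        res = bm.agreement_analysis(flags, flags)
        assert res.balanced_accuracy == 1.0 and res.accuracy == 1.0

    def test_counts_against_reference(self):
        res = bm.agreement_analysis([True, True, False, False], [True, False, True, False])
        cm = res.matrix
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)
        assert res.balanced_accuracy == 0.5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 20), st.integers(0, 2**31 - 1))
    def test_balanced_accuracy_invariant_to_duplication(self, k, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(12) < 0.5
        r = rng.random(12) < 0.5
        if r.all() or (~r).all():
            return
        ba1 = bm.agreement_analysis(a, r).balanced_accuracy
        bak = bm.agreement_analysis(np.tile(a, k), np.tile(r, k)).balanced_accuracy
        assert bak == pytest.approx(ba1, abs=1e-12)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            bm.agreement_analysis([True], [True, False])
        with pytest.raises(ValueError):
            bm.agreement_analysis([], [])

    def test_confusion_matrix_round_trip_through_flags(self):
        cm = bm.ConfusionMatrix(tn=10, fn=3, fp=2, tp=7)
        res = bm.agreement_analysis(*cm.to_flags())
        assert res.matrix == cm


class TestAriesGraderCounts:
    """The shipped ARIES grader-agreement matrices reproduce the study values."""

    @pytest.mark.parametrize("key, expected_ba", [
        (("study_site", "irf_presence"), 0.75),
        (("ai", "irf_presence"), 0.86),
        (("study_site", "srf_height_ge_50um"), 0.81),
        (("ai", "srf_height_ge_50um"), 0.79),
        (("ai", "srf_presence"), 0.85),
    ])
    def test_balanced_accuracy(self, key, expected_ba):
        cm = bm.ARIES_GRADER_AGREEMENT[key]
        res = bm.agreement_analysis(*cm.to_flags())
        assert abs(res.balanced_accuracy - expected_ba) <= 0.005 + 1e-9

    def test_reading_center_marginals_consistent(self):
        """Both raters grade the same reading-center SRF-height set."""
        site = bm.ARIES_GRADER_AGREEMENT[("study_site", "srf_height_ge_50um")]
        ai = bm.ARIES_GRADER_AGREEMENT[("ai", "srf_height_ge_50um")]
        assert site.tn + site.fp == ai.tn + ai.fp
        assert site.fn + site.tp == ai.fn + ai.tp


class TestStandinSegmenter:
    def test_zero_fluid_scan_empty(self, device):
        vol, mask = render_scan(FluidState.from_volumes(0, 0), device, seed=11)
        seg = bm.segment_fluid_standin(vol, mask.layers)
        assert seg.labels.sum() == 0

    def test_min_size_filter_removes_small_components(self, device):
        vol, mask = render_scan(FluidState.from_volumes(8, 0), device, seed=12)
        params = bm.SegmentationParams(min_size=10**6)
        seg = bm.segment_fluid_standin(vol, mask.layers, params)
        assert seg.labels.sum() == 0

    def test_dice_above_080_on_synthetic_cohort(self, device, scan_bank):
        """Voxelwise Dice vs the renderer's ground truth on 50 default scans."""
        scans = scan_bank.scans(50, seed=7, device=device)
        for lab in (bm.IRF_LABEL, bm.SRF_LABEL):
            dices = []
            for _, vol, mask in scans:
                gt = mask.labels == lab
                if gt.sum() < 100:
                    continue
                seg = bm.segment_fluid_standin(vol, mask.layers)
                dices.append(bm.dice_coefficient(seg.labels == lab, gt))
            assert dices, "cohort must contain pockets >= 100 voxels"
            assert float(np.mean(dices)) >= 0.80

    def test_missing_layers_rejected(self, device):
        vol, _ = render_scan(FluidState.from_volumes(1, 1), device, seed=13)
        with pytest.raises(ValueError):
            bm.segment_fluid_standin(vol, None)


class TestThresholdRecovery:
    def test_eer_recovers_generating_presence_cut(self, device, scan_bank):
        """Calibrating on measured volumes vs true presence lands near 6/16 nL."""
        from octneed.biomarkers import DEFAULT_THRESHOLDS_NL

        for seed in (7, 21):
            scans = scan_bank.scans(120, seed=seed, device=device)
            measured = {"irf": [], "srf": []}
            truth = {"irf": [], "srf": []}
            for state, vol, mask in scans:
                seg = bm.segment_fluid_standin(vol, mask.layers)
                m = bm.compute_fluid_metrics(seg)
                measured["irf"].append(m.irf_volume_nl)
                measured["srf"].append(m.srf_volume_nl)
                truth["irf"].append(state.irf_volume_nl >= DEFAULT_THRESHOLDS_NL["irf"])
                truth["srf"].append(state.srf_volume_nl >= DEFAULT_THRESHOLDS_NL["srf"])
            for comp in ("irf", "srf"):
                t = bm.calibrate_eer_threshold(measured[comp], truth[comp])
                assert abs(t - DEFAULT_THRESHOLDS_NL[comp]) < 0.15 * DEFAULT_THRESHOLDS_NL[comp]
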