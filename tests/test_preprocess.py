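"""Preprocessing chain: geometry, CLAHE, flattening, model-input contract."""

import numpy as np
import pytest

from octneed import preprocess as pp
from octneed.cohort import DeviceProfile, FluidState
from octneed.render import render_scan


def _flat_layers(n, cols, ilm=40.0, spread=(0, 10, 20, 40, 43)):
    names = ("ilm", "ipl", "opl", "rpe", "bm")
    return pp.LayerSet({k: np.full((n, cols), ilm + off) for k, off in zip(names, spread)})


def _vol(data, spacings=(120.0, 7.0, 26.25)):
    return pp.OCTVolume(np.asarray(data, dtype=np.float32), spacings)


class TestNormalizeGeometry:
    def test_reference_volume_unchanged(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.random((30, 64, 128)))
        out, _, _ = pp.normalize_geometry(v)
        assert out.shape == v.shape
        np.testing.assert_allclose(out.intensities, v.intensities, atol=1e-6)

    def test_double_lateral_pitch_doubles_width(self):
        """A scan at 2x the reference pitch covers 2x mm; resampling doubles px."""
        v = _vol(np.random.default_rng(1).random((29, 64, 64)), (120.0, 7.0, 52.5))
        out, _, _ = pp.normalize_geometry(v)
        # 64 px at 52.5 um = 3.36 mm -> exactly the FoV at 26.25 um/px = 128 px
        assert out.shape == (29, 64, 128)
        assert out.spacings[2] == 26.25

    def test_zero_volume_stays_zero(self):
        v = _vol(np.zeros((28, 32, 100)), (120.0, 14.0, 26.25))
        out, _, _ = pp.normalize_geometry(v)
        assert out.intensities.min() == out.intensities.max() == 0.0
        assert out.shape[2] == 128  # padded to the 3.36 mm field of view

    def test_missing_spacings_rejected(self):
        with pytest.raises(ValueError):
            pp.OCTVolume(np.zeros((2, 4, 4)), (0.0, 7.0, 26.25))


class TestSelectCentralBscans:
    def test_identity_on_28(self):
        v = _vol(np.random.default_rng(0).random((28, 16, 16)))
        out, _, _ = pp.select_central_bscans(v, 28)
        assert np.array_equal(out.intensities, v.intensities)

    def test_97_scan_window_is_34_to_61(self):
        data = np.zeros((97, 4, 4), dtype=np.float32)
        data[:, 0, 0] = np.arange(97) / 100.0
        out, _, _ = pp.select_central_bscans(_vol(data), 28)
        np.testing.assert_allclose(out.intensities[:, 0, 0] * 100, np.arange(34, 62))

    def test_too_few_bscans_error(self):
        with pytest.raises(ValueError):
            pp.select_central_bscans(_vol(np.zeros((27, 4, 4))), 28)


class TestDetectROI:
    def test_flat_layers_zero_margin(self):
        v = _vol(np.zeros((3, 100, 20)))
        boxes = pp.detect_roi(v, _flat_layers(3, 20), margin_um=0.0)
        assert boxes[0][0] == 40 and boxes[0][1] == 84  # ILM row .. BM row (+1)

    def test_tilted_layers_cover_extreme_rows(self):
        layers = _flat_layers(2, 50)
        tilt = np.arange(50) * 0.5
        layers = pp.LayerSet({k: v + tilt for k, v in layers.surfaces.items()})
        v = _vol(np.zeros((2, 200, 50)))
        boxes = pp.detect_roi(v, layers, margin_um=0.0)
        assert boxes[0][0] == int(np.floor(layers["ilm"].min()))
        assert boxes[0][1] == int(np.ceil(layers["bm"].max())) + 1

    def test_huge_margin_clamps_to_image(self):
        v = _vol(np.zeros((2, 60, 20)))
        boxes = pp.detect_roi(v, _flat_layers(2, 20), margin_um=1e6)
        assert boxes[0][0] == 0 and boxes[0][1] == 60


class TestCLAHE:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.4)
        np.testing.assert_array_equal(pp.apply_clahe(img), img)

    def test_output_in_unit_range(self):
        img = np.random.default_rng(0).random((96, 96))
        out = pp.apply_clahe(img)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_step_separation_not_decreased(self):
        """Histogram equalization spreads a two-level image at least as far."""
        img = np.full((64, 64), 0.45)
        img[:, 32:] = 0.55
        out = pp.apply_clahe(img, clip_limit=0.05)
        sep_in = img[:, 48:].mean() - img[:, :16].mean()
        sep_out = out[:, 48:].mean() - out[:, :16].mean()
        assert sep_out >= sep_in - 1e-6

    def test_invalid_clip_limit(self):
        with pytest.raises(ValueError):
            pp.apply_clahe(np.zeros((8, 8)), clip_limit=0.0)


class TestAlignSlices:
    def test_flat_bm_at_reference_is_identity(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.random((3, 100, 20)))
        layers = _flat_layers(3, 20, ilm=40.0)  # bm at 83
        out, out_layers, _ = pp.align_slices(v, layers, reference_row=83)
        np.testing.assert_array_equal(out.intensities, v.intensities)
        np.testing.assert_allclose(out_layers["bm"], 83.0)

    def test_sloped_bm_shifts_each_column(self):
        """BM sloping 1 px/column: column j must shift by ref - (b0 + j) rows."""
        rng = np.random.default_rng(1)
        data = rng.random((1, 80, 30)).astype(np.float32)
        v = _vol(data)
        b0 = 30.0
        names = ("ilm", "ipl", "opl", "rpe", "bm")
        layers = pp.LayerSet({k: (b0 - 25 + i * 6) + np.arange(30)[None, :]
                              for i, k in enumerate(names)})
        ref = 50
        bm_before = layers["bm"].copy()
        out, out_layers, _ = pp.align_slices(v, layers, reference_row=ref)
        for j in range(30):
            s = int(round(ref - bm_before[0, j]))
            expected = np.zeros(80, dtype=np.float32)
            src0, src1 = max(0, -s), min(80, 80 - s)
            expected[src0 + s:src1 + s] = data[0, src0:src1, j]
            np.testing.assert_array_equal(out.intensities[0, :, j], expected)
        np.testing.assert_allclose(out_layers["bm"], ref, atol=0.5)

    def test_zero_image_stays_zero(self):
        v = _vol(np.zeros((2, 50, 10)))
        out, _, _ = pp.align_slices(v, _flat_layers(2, 10), reference_row=45)
        assert not out.intensities.any()

    def test_nan_bm_interpolated_across_columns(self):
        v = _vol(np.random.default_rng(0).random((1, 60, 9)))
        layers = _flat_layers(1, 9)
        bm = layers["bm"].copy()
        bm[0, 4] = np.nan
        layers.surfaces["bm"] = bm
        out, out_layers, _ = pp.align_slices(v, layers, reference_row=50)
        bm_out = out_layers["bm"][0]
        np.testing.assert_allclose(bm_out[np.isfinite(bm_out)], 50.0, atol=0.5)
        # the untraced column is shifted by the laterally interpolated value
        assert np.array_equal(out.intensities[0, :, 4] != 0,
                              out.intensities[0, :, 3] != 0)

    def test_fully_missing_bm_errors(self):
        v = _vol(np.zeros((1, 60, 9)))
        layers = _flat_layers(1, 9)
        layers.surfaces["bm"] = np.full((1, 9), np.nan)
        with pytest.raises(ValueError):
            pp.align_slices(v, layers, reference_row=50)


class TestBuildModelInput:
    def test_shape_contract(self):
        v = _vol(np.random.default_rng(0).random((28, 100, 100)))
        mi, _ = pp.build_model_input(v)
        assert mi.volume.shape == (28, 52, 72)

    def test_constant_volume_preserved(self):
        v = _vol(np.full((28, 64, 64), 0.5, dtype=np.float32))
        mi, _ = pp.build_model_input(v)
        np.testing.assert_allclose(mi.volume, 0.5, atol=1e-6)

    def test_impulse_lands_at_predicted_crop_coordinates(self):
        """A bright pixel at (60, 64) of the 128 grid appears at (60-42, 64-28)."""
        data = np.zeros((28, 128, 128), dtype=np.float32)
        data[5, 60, 64] = 1.0
        mi, _ = pp.build_model_input(_vol(data))
        r0, c0 = pp.CROP_ROWS[0], pp.CROP_COLS[0]
        assert mi.volume[5, 60 - r0, 64 - c0] == pytest.approx(1.0)
        assert mi.volume.sum() == pytest.approx(1.0)

    def test_wrong_bscan_count_rejected(self):
        with pytest.raises(ValueError):
            pp.build_model_input(_vol(np.zeros((27, 64, 64))))


class TestChain:
    def test_shape_contract_across_devices(self):
        for dev in (DeviceProfile(),
                    DeviceProfile(axial_um_per_px=3.5, lateral_um_per_px=11.7,
                                  bscan_spacing_um=110.0, n_bscans=33,
                                  height_px=384, width_px=290)):
            vol, mask = render_scan(FluidState.from_volumes(8, 18), dev, seed=1)
            mi = pp.preprocess_volume(vol, mask.layers)
            assert mi.volume.shape == (28, 52, 72)

    def test_geometric_chain_idempotent(self, device):
        """Re-running the geometric stages on their own output is the identity."""
        vol, mask = render_scan(FluidState.from_volumes(6, 20), device, seed=2)
        cfg = pp.PreprocessConfig(apply_clahe=False)

        def geometric(v, l):
            v, l, _ = pp.normalize_geometry(v, l, config=cfg)
            v, l, _ = pp.select_central_bscans(v, cfg.n_bscans, l)
            boxes = pp.detect_roi(v, l, cfg.roi_margin_um)
            boxes = pp._round_roi_rows(boxes, pp.RESIZE_PX, v.shape[1])
            v, l, _ = pp.crop_to_roi(v, boxes, l)
            ref = int(round(pp.BM_REFERENCE_ROW / pp.RESIZE_PX * v.shape[1]))
            return pp.align_slices(v, l, ref)[:2]

        v1, l1 = geometric(vol, mask.layers)
        v2, l2 = geometric(v1, l1)
        assert v2.shape == v1.shape
        np.testing.assert_allclose(v2.intensities, v1.intensities, atol=1e-6)

    def test_mask_volume_preserved_within_5_percent(self, device):
        """Physical fluid volume survives the geometric co-transformations."""
        for seed in (0, 3, 5):
            vol, mask = render_scan(FluidState.from_volumes(12, 20), device, seed=seed)
            mi = pp.preprocess_volume(vol, mask.layers, mask.labels)
            out = mi.provenance["mask"]
            rows, cols = mi.provenance["pre_resize_shape"]
            cfg = pp.PreprocessConfig()
            vox_after = (device.bscan_spacing_um
                         * cfg.reference_axial_um * rows / pp.RESIZE_PX
                         * cfg.reference_lateral_um * cols / pp.RESIZE_PX)
            vox_before = np.prod(vol.spacings)
            for lab in (1, 2):
                before = (mask.labels == lab).sum() * vox_before
                after = (out == lab).sum() * vox_after
                if before >= 50 * vox_before:
                    assert abs(after - before) / before < 0.05
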