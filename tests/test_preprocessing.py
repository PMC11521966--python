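"""Pre-processing: region extraction, cleanup, amplitude features."""

import numpy as np
import pytest

from fetaldoppler import preprocessing as pre
from fetaldoppler import synthetic as syn
from fetaldoppler.calibration import Calibration
from conftest import to_grey


def _composite(bmode_rgb, doppler_rgb):
    """Stack two RGB regions vertically into one capture with known boxes."""
    hb, wb = bmode_rgb.shape[:2]
    hd, wd = doppler_rgb.shape[:2]
    W = max(wb, wd)
    raw = np.zeros((hb + hd, W, 3))
    raw[:hb, :wb] = bmode_rgb
    raw[hb : hb + hd, :wd] = doppler_rgb
    meta = {
        "is_single_frame": True,
        "bmode": {"box": (0, 0, hb, wb)},
        "doppler": {"box": (hb, 0, hb + hd, wd), "time_per_px": 2.0, "vel_per_px": 0.5, "zero_line_row": 128},
    }
    return raw, meta


class TestExtractRegions:
    def test_identity_crop_and_calibration(self, rng):
        b = rng.random((64, 64, 3))
        d = rng.random((128, 256, 3))
        raw, meta = _composite(b, d)
        bc, dc, cal = pre.extract_regions(raw, meta)
        assert np.array_equal(bc, b)
        assert np.array_equal(dc, d)
        assert cal == Calibration(2.0, 0.5, 128)

    def test_missing_region_rejected(self, rng):
        raw, meta = _composite(rng.random((8, 8, 3)), rng.random((8, 8, 3)))
        del meta["doppler"]
        with pytest.raises(ValueError, match="region not found"):
            pre.extract_regions(raw, meta)

    def test_multi_frame_rejected(self, rng):
        raw, meta = _composite(rng.random((8, 8, 3)), rng.random((8, 8, 3)))
        meta["is_single_frame"] = False
        with pytest.raises(ValueError, match="single-frame"):
            pre.extract_regions(raw, meta)


class TestBurnedAnnotations:
    def test_yellow_text_block_replaced(self):
        img = np.full((32, 32, 3), 0.4)
        img[5:10, 5:20] = [0.95, 0.85, 0.1]
        out = pre.remove_burned_annotations(img, [(0.95, 0.85, 0.1)], tolerance=0.05)
        spread = out.max(axis=2) - out.min(axis=2)
        assert np.all(spread <= 0.05)

    def test_all_black_rows_dropped(self):
        img = np.full((16, 16, 3), 0.5)
        img[-3:] = 0.0
        out = pre.remove_burned_annotations(img, [])
        assert out.shape[0] == 13

    def test_pure_grey_unchanged(self):
        img = np.full((16, 16, 3), 0.5)
        out = pre.remove_burned_annotations(img, [(1.0, 0.6, 0.1)])
        assert np.array_equal(out, img)


class TestCursorMask:
    def test_matches_simulator_ground_truth(self):
        rgb, truth = syn.render_bmode_with_cursor("UA", "dashed_line", np.random.default_rng(0))
        mask = pre.detect_cursor_mask(rgb)
        assert np.array_equal(mask, truth["cursor_mask"])

    def test_bounding_box_cursor_detected(self):
        rgb, truth = syn.render_bmode_with_cursor("AoI", "bounding_box", np.random.default_rng(2))
        mask = pre.detect_cursor_mask(rgb)
        assert np.array_equal(mask, truth["cursor_mask"])

    def test_grey_image_warns_and_returns_empty(self, caplog):
        img = np.full((8, 8, 3), 0.3)
        with caplog.at_level("WARNING"):
            mask = pre.detect_cursor_mask(img)
        assert not mask.any()
        assert "no cursor detected" in caplog.text

    def test_combine_sets_cursor_to_full_intensity(self):
        grey = np.full((4, 4), 0.2)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        out = pre.combine_cursor(grey, mask)
        assert out[1, 1] == 1.0 and out[0, 0] == 0.2


class TestBinarizeAndMetrics:
    def test_threshold_rule(self):
        img = np.array([[0.05, 0.5], [0.0, 0.2]])
        out = pre.binarize_doppler(img, 0.1)
        assert out.tolist() == [[False, True], [False, True]]

    def test_noiseless_spectrogram_matches_fill_mask(self, ua_studies):
        st = ua_studies[0]
        binary = pre.binarize_doppler(st.doppler, 0.1)
        assert np.array_equal(binary, st.truth["fill_mask"])

    def test_pixel_scan_oracle(self):
        # zero line at row 5 of 10 rows; signal rows 1..4 above, 6..8 below
        binary = np.zeros((10, 4), dtype=bool)
        binary[1:5, 0] = True
        binary[6:9, 2] = True
        f = pre.extract_velocity_metrics(binary, Calibration(1.0, 1.0, 5))
        assert f.v_max == 4.0 and f.v_min == 3.0 and f.v_range == 7.0
        assert f.row_span == (1, 8)

    def test_one_sided_signal(self):
        binary = np.zeros((10, 4), dtype=bool)
        binary[2:5, 1] = True
        f = pre.extract_velocity_metrics(binary, Calibration(1.0, 1.0, 5))
        assert f.v_min == 0.0 and f.v_range == f.v_max == 3.0

    def test_empty_raster_rejected(self):
        with pytest.raises(ValueError, match="no Doppler signal"):
            pre.extract_velocity_metrics(np.zeros((4, 4), dtype=bool), Calibration(1, 1, 2))

    def test_vertical_flip_swaps_extremes(self, rng):
        for _ in range(20):
            binary = rng.random((31, 8)) > 0.7
            binary[15] = False  # keep the zero line clear
            if not binary.any():
                continue
            cal = Calibration(1.0, 0.7, 15)
            f = pre.extract_velocity_metrics(binary, cal)
            g = pre.extract_velocity_metrics(binary[::-1], cal)
            assert g.v_max == pytest.approx(f.v_min)
            assert g.v_min == pytest.approx(f.v_max)
            assert g.v_range == pytest.approx(f.v_range)

    def test_recovers_simulator_peaks(self, mixed_studies):
        studies, _ = mixed_studies
        for st in studies:
            if st.view == "OTHER":
                continue
            binary = pre.binarize_doppler(st.doppler, 0.1)
            f = pre.extract_velocity_metrics(binary, st.calibration)
            env = np.array(st.truth["envelope_v"])
            vmax_true = max(env.max(), 0.0)
            vmin_true = max(-env.min(), 0.0)
            tol = st.calibration.vel_per_px
            assert f.v_max == pytest.approx(vmax_true, abs=tol)
            assert f.v_min == pytest.approx(vmin_true, abs=tol)


class TestNormalizeRegion:
    def test_min_max_range(self, rng):
        img = rng.random((64, 64)) * 100 + 10
        out = pre.normalize_region(img, (32, 32))
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)

    def test_constant_image_maps_to_zeros(self):
        out = pre.normalize_region(np.full((16, 16), 7.0), (8, 8))
        assert np.all(out == 0.0)

    def test_resize_rescales_calibration(self, rng):
        img = rng.random((512, 1024))
        cal = Calibration(2.0, 0.5, 256)
        out, cal2 = pre.normalize_region(img, (256, 512), cal)
        assert out.shape == (256, 512)
        assert cal2.time_per_px == pytest.approx(4.0)
        assert cal2.vel_per_px == pytest.approx(1.0)
        assert cal2.zero_line_row == pytest.approx(128)
        # physical duration preserved within one pixel of time
        assert 512 * cal2.time_per_px == pytest.approx(1024 * cal.time_per_px, abs=cal2.time_per_px)

    def test_idempotent_at_target_shape(self, rng):
        img = rng.random((64, 64))
        once = pre.normalize_region(img, (64, 64))
        twice = pre.normalize_region(once, (64, 64))
        assert np.allclose(once, twice, atol=1e-12)


class TestPreprocessStudy:
    def test_full_chain_shapes_and_range(self, rng):
        bmode, _ = syn.render_bmode_with_cursor("UA", "dashed_line", np.random.default_rng(3))
        doppler = np.repeat(rng.random((128, 256))[:, :, None], 3, axis=2)
        raw, meta = _composite(bmode, doppler)
        meta["doppler"]["zero_line_row"] = 100
        study = pre.preprocess_study(raw, meta, source_id="t1")
        assert study.bmode.shape == (256, 256)
        assert study.doppler.shape == (256, 512)
        assert 0.0 <= study.bmode.min() and study.bmode.max() <= 1.0
        assert study.cursor_mask.shape == (256, 256)
        assert study.is_single_frame


class TestDicomRegions:
    @staticmethod
    def _dicom_dataset(n_frames=None):
        """In-memory stand-in for a pydicom dataset: pydicom region items
        plus a plain pixel array (pixel decoding itself is not under test)."""
        from types import SimpleNamespace

        from pydicom.dataset import Dataset

        rng = np.random.default_rng(0)
        pixels = (rng.random((96, 128, 3)) * 255).astype(np.uint8)

        bmode = Dataset()
        bmode.RegionDataType = 1
        bmode.RegionLocationMinX0, bmode.RegionLocationMinY0 = 0, 0
        bmode.RegionLocationMaxX1, bmode.RegionLocationMaxY1 = 63, 47

        spectral = Dataset()
        spectral.RegionDataType = 3
        spectral.RegionLocationMinX0, spectral.RegionLocationMinY0 = 0, 48
        spectral.RegionLocationMaxX1, spectral.RegionLocationMaxY1 = 127, 95
        spectral.PhysicalDeltaX = 0.002  # s/px
        spectral.PhysicalDeltaY = -0.5  # cm/s per px
        spectral.ReferencePixelY0 = 24

        ds = SimpleNamespace(
            SequenceOfUltrasoundRegions=[bmode, spectral],
            pixel_array=pixels,
        )
        if n_frames is not None:
            ds.NumberOfFrames = n_frames
        return ds

    def test_region_metadata_from_ultrasound_regions(self):
        ds = self._dicom_dataset()
        raw, meta = pre.regions_from_dicom(ds)
        assert meta["is_single_frame"]
        assert meta["bmode"]["box"] == (0, 0, 48, 64)
        assert meta["doppler"]["box"] == (48, 0, 96, 128)
        assert meta["doppler"]["time_per_px"] == pytest.approx(2.0)  # ms
        assert meta["doppler"]["vel_per_px"] == pytest.approx(0.5)
        assert meta["doppler"]["zero_line_row"] == 24
        bc, dc, cal = pre.extract_regions(raw, meta)
        assert bc.shape[:2] == (48, 64) and dc.shape[:2] == (48, 128)

    def test_multi_frame_flagged(self):
        ds = self._dicom_dataset(n_frames=12)
        raw, meta = pre.regions_from_dicom(ds)
        assert not meta["is_single_frame"]
        with pytest.raises(ValueError, match="single-frame"):
            pre.extract_regions(raw, meta)


def test_zero_line_fallback_estimate():
    binary = np.zeros((21, 50), dtype=bool)
    binary[6:10, :] = True  # above
    binary[11:15, :] = True  # below, symmetric about row 10
    assert abs(pre.estimate_zero_line(binary) - 10) <= 1
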