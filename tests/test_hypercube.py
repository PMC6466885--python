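"""ENVI round trips, black/white calibration, band cropping and ROI means."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hyperssc import (
    HyperCube,
    ReferenceFrames,
    ROISpec,
    calibrate_reflectance,
    center_roi_on_mask,
    crop_bands,
    extract_roi_mean,
    read_envi,
    write_envi,
)

WL3 = np.array([900.0, 1000.0, 1100.0])


def _cube(data, wl=None, flavor="raw"):
    data = np.asarray(data)
    wl = np.arange(data.shape[2], dtype=float) * 50 + 900 if wl is None else wl
    return HyperCube(data, wl, flavor=flavor)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bil", "bsq", "bip"])
    @pytest.mark.parametrize("dtype", [np.uint16, np.float32])
    def test_round_trip_identity(self, tmp_path, interleave, dtype):
        rng = np.random.default_rng(0)
        data = (rng.random((4, 5, 3)) * 1000).astype(dtype)
        cube = _cube(data, WL3)
        hdr = str(tmp_path / f"cube_{interleave}.hdr")
        write_envi(cube, hdr, interleave=interleave)
        back = read_envi(hdr)
        np.testing.assert_array_equal(back.data, data)
        np.testing.assert_allclose(back.wavelengths, WL3)

    def test_interleave_equivalence(self, tmp_path):
        data = np.arange(60, dtype=np.float32).reshape(4, 5, 3)
        cubes = []
        for il in ("bil", "bsq"):
            hdr = str(tmp_path / f"c_{il}.hdr")
            write_envi(_cube(data, WL3), hdr, interleave=il)
            cubes.append(read_envi(hdr).data)
        np.testing.assert_array_equal(cubes[0], cubes[1])

    def test_wavelength_count_mismatch_rejected(self, tmp_path):
        hdr = str(tmp_path / "c.hdr")
        write_envi(_cube(np.zeros((4, 5, 3), np.float32), WL3), hdr)
        text = open(hdr).read().replace("1100.0000", "")
        open(hdr, "w").write(text.replace("1000.0000,", "1000.0000"))
        with pytest.raises(ValueError, match="wavelength"):
            read_envi(hdr)

    def test_missing_binary_rejected(self, tmp_path):
        hdr = str(tmp_path / "c.hdr")
        write_envi(_cube(np.zeros((4, 5, 3), np.float32), WL3), hdr)
        (tmp_path / "c.img").unlink()
        with pytest.raises(FileNotFoundError):
            read_envi(hdr)

    def test_truncated_binary_rejected(self, tmp_path):
        hdr = str(tmp_path / "c.hdr")
        write_envi(_cube(np.zeros((4, 5, 3), np.float32), WL3), hdr)
        raw = (tmp_path / "c.img").read_bytes()
        (tmp_path / "c.img").write_bytes(raw[:-8])
        with pytest.raises(ValueError, match="holds"):
            read_envi(hdr)

    def test_unsupported_interleave_and_dtype_rejected(self, tmp_path):
        hdr = str(tmp_path / "c.hdr")
        write_envi(_cube(np.zeros((4, 5, 3), np.float32), WL3), hdr)
        text = open(hdr).read()
        open(hdr, "w").write(text.replace("interleave = bil", "interleave = weird"))
        with pytest.raises(ValueError, match="interleave"):
            read_envi(hdr)
        open(hdr, "w").write(text.replace("data type = 4", "data type = 5"))
        with pytest.raises(ValueError, match="data type"):
            read_envi(hdr)


class TestCalibration:
    def test_white_identity(self):
        raw = _cube(np.full((3, 4, 2), 0.9))
        refs = ReferenceFrames(np.full((3, 4, 2), 0.1), np.full((3, 4, 2), 0.9))
        np.testing.assert_allclose(calibrate_reflectance(raw, refs).data, 1.0)

    def test_dark_identity(self):
        raw = _cube(np.full((3, 4, 2), 0.1))
        refs = ReferenceFrames(np.full((3, 4, 2), 0.1), np.full((3, 4, 2), 0.9))
        np.testing.assert_allclose(calibrate_reflectance(raw, refs).data, 0.0)

    def test_direct_arithmetic(self):
        raw = _cube(np.full((2, 2, 2), 0.5))
        refs = ReferenceFrames(np.full((2, 2, 2), 0.1), np.full((2, 2, 2), 0.9))
        out = calibrate_reflectance(raw, refs)
        np.testing.assert_allclose(out.data, 0.5)
        assert out.flavor == "reflectance"

    def test_idempotent_with_unit_references(self, rng):
        data = rng.random((3, 4, 5))
        raw = _cube(data)
        refs = ReferenceFrames(np.zeros((3, 4, 5)), np.ones((3, 4, 5)))
        np.testing.assert_allclose(calibrate_reflectance(raw, refs).data, data)

    def test_per_band_vector_references(self, rng):
        data = rng.random((3, 4, 5))
        dark, white = np.full(5, 0.1), np.linspace(0.8, 1.0, 5)
        out = calibrate_reflectance(_cube(data), ReferenceFrames(dark, white))
        np.testing.assert_allclose(out.data, (data - dark) / (white - dark))

    def test_nonpositive_denominator_names_location(self):
        dark = np.full((2, 2, 2), 0.1)
        white = np.full((2, 2, 2), 0.9)
        white[1, 0, 1] = 0.05
        with pytest.raises(ValueError, match=r"\(1, 0, 1\)"):
            calibrate_reflectance(_cube(np.zeros((2, 2, 2))), ReferenceFrames(dark, white))

    def test_requires_raw_flavor(self):
        refl = _cube(np.full((2, 2, 2), 0.5), flavor="reflectance")
        with pytest.raises(ValueError, match="raw"):
            calibrate_reflectance(refl, ReferenceFrames(np.zeros(2), np.ones(2)))


class TestCropBands:
    WL = np.array([900.0, 950.0, 1300.0, 1675.0, 1700.0])

    def _cube5(self):
        return HyperCube(np.random.default_rng(0).random((2, 2, 5)), self.WL)

    def test_boundary_inclusion(self):
        out = crop_bands(self._cube5(), 950, 1675)
        np.testing.assert_allclose(out.wavelengths, [950, 1300, 1675])

    def test_full_range_identity(self):
        cube = self._cube5()
        out = crop_bands(cube, 900, 1700)
        np.testing.assert_array_equal(out.data, cube.data)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no bands"):
            crop_bands(self._cube5(), 2000, 2100)

    @given(
        lo=st.floats(900, 1200),
        width=st.floats(100, 500),
        inner_lo=st.floats(0, 100),
        inner_width=st.floats(50, 200),
    )
    def test_nested_crops_collapse(self, lo, width, inner_lo, inner_width):
        """crop(crop(X, outer), inner) == crop(X, inner) for nested ranges."""
        cube = HyperCube(np.ones((2, 2, 40)), np.linspace(900, 1700, 40))
        hi = lo + width
        ilo, ihi = lo + inner_lo, min(lo + inner_lo + inner_width, hi)
        try:
            once = crop_bands(cube, ilo, ihi)
            twice = crop_bands(crop_bands(cube, lo, hi), ilo, ihi)
        except ValueError:
            return  # empty selection is a legal outcome for arbitrary ranges
        np.testing.assert_array_equal(once.wavelengths, twice.wavelengths)


class TestRoiMean:
    def test_constant_cube(self):
        cube = _cube(np.full((20, 40, 3), 0.7), flavor="reflectance")
        np.testing.assert_allclose(extract_roi_mean(cube, ROISpec(2, 5, 15, 30)), 0.7)

    def test_two_pixel_mean(self):
        data = np.array([[[0.2, 0.4]], [[0.6, 0.8]]])  # 2 x 1 x 2
        cube = _cube(data, np.array([900.0, 1000.0]), flavor="reflectance")
        np.testing.assert_allclose(extract_roi_mean(cube, ROISpec(0, 0, 2, 1)), [0.4, 0.6])

    def test_matches_bruteforce_loop(self, rng):
        cube = _cube(rng.random((30, 50, 8)), flavor="reflectance")
        roi = ROISpec(4, 7, 15, 30)
        mean = extract_roi_mean(cube, roi)
        expected = np.zeros(8)
        for r in range(roi.row0, roi.row0 + roi.height):
            for c in range(roi.col0, roi.col0 + roi.width):
                expected += cube.data[r, c]
        expected /= roi.height * roi.width
        np.testing.assert_allclose(mean, expected, atol=1e-10)

    def test_roi_outside_extent_rejected(self):
        cube = _cube(np.ones((10, 10, 2)), flavor="reflectance")
        with pytest.raises(ValueError, match="extent"):
            extract_roi_mean(cube, ROISpec(0, 0, 15, 30))

    def test_center_roi_on_mask(self):
        mask = np.zeros((60, 80), dtype=bool)
        mask[20:50, 25:65] = True
        roi = center_roi_on_mask(mask, 15, 30)
        assert (roi.row0, roi.col0) == (27, 30)  # centered on centroid (34.5, 44.5)


def test_cube_invariants_enforced():
    with pytest.raises(ValueError, match="increasing"):
        HyperCube(np.ones((2, 2, 2)), np.array([1000.0, 900.0]))
    with pytest.raises(ValueError, match="band count"):
        HyperCube(np.ones((2, 2, 3)), np.array([900.0, 1000.0]))
    with pytest.raises(ValueError, match="finite"):
        HyperCube(np.full((1, 1, 1), np.nan), np.array([900.0]), flavor="reflectance")
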