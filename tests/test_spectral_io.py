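"""Spectral containers, CSV/ENVI round trips, clipping and resampling."""

import numpy as np
import pytest

from m2hsn import (
    Cube,
    SpectraSet,
    Spectrum,
    WavelengthGrid,
    clip_to_range,
    read_envi_cube,
    read_spectral_library,
    resample_to_grid,
    write_envi_cube,
    write_spectral_library,
)
from m2hsn.errors import (
    CoverageError,
    DegenerateGridError,
    DimensionError,
    FormatError,
)


class TestContainers:
    def test_grid_rejects_non_monotone(self):
        with pytest.raises(FormatError):
            WavelengthGrid(np.array([500.0, 400.0]))

    def test_spectrum_length_must_match_grid(self):
        grid = WavelengthGrid(np.array([400.0, 500.0]))
        with pytest.raises(DimensionError):
            Spectrum(grid, np.array([0.1, 0.2, 0.3]))

    def test_out_of_range_reflectance_warns_but_keeps(self):
        grid = WavelengthGrid(np.array([400.0, 500.0]))
        with pytest.warns(UserWarning, match="reflectance"):
            s = Spectrum(grid, np.array([0.1, 2.0]))
        assert s.reflectance[1] == 2.0

    def test_cube_spectraset_bijection(self):
        grid = WavelengthGrid(np.array([400.0, 500.0, 600.0]))
        values = np.arange(2 * 3 * 3, dtype=float).reshape(2, 3, 3) / 100
        cube = Cube(grid, values)
        back = Cube.from_spectra_set(cube.to_spectra_set(), 2, 3)
        np.testing.assert_array_equal(back.values, cube.values)

    def test_duplicate_coordinates_rejected(self):
        grid = WavelengthGrid(np.array([400.0, 500.0]))
        with pytest.raises(DimensionError):
            SpectraSet(grid, np.zeros((2, 2)), coords=np.array([[0, 0], [0, 0]]))


class TestSpectralLibraryCsv:
    def test_round_trip(self, tmp_path):
        grid = WavelengthGrid(np.array([400.0, 500.0, 600.0]))
        original = SpectraSet(grid, np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]]),
                              ids=["a", "b"])
        path = tmp_path / "lib.csv"
        write_spectral_library(original, path)
        back = read_spectral_library(path)
        assert back.grid == grid
        np.testing.assert_allclose(back.values, original.values, atol=1e-12)
        assert back.ids == ["a", "b"]

    def test_non_monotone_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,s\n500,0.1\n400,0.2\n")
        with pytest.raises(FormatError):
            read_spectral_library(path)

    def test_wavelength_only_file_has_zero_spectra(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("wavelength_nm\n400\n500\n")
        spectra = read_spectral_library(path)
        assert len(spectra) == 0

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("wavelength_nm,s\n400,0.1\n500\n")
        with pytest.raises(FormatError):
            read_spectral_library(path)

    def test_single_band_grid(self, tmp_path):
        grid = WavelengthGrid(np.array([700.0]))
        original = SpectraSet(grid, np.array([[0.5]]))
        path = tmp_path / "one.csv"
        write_spectral_library(original, path)
        assert len(path.read_text().strip().splitlines()) == 2  # header + one row


class TestEnvi:
    def test_round_trip_bsq(self, tmp_path):
        grid = WavelengthGrid(np.array([450.0, 550.0, 650.0]))
        values = np.arange(2 * 2 * 3, dtype=float).reshape(2, 2, 3) / 20
        cube = Cube(grid, values)
        write_envi_cube(cube, tmp_path / "cube.bsq")
        back = read_envi_cube(tmp_path / "cube.hdr")
        np.testing.assert_allclose(back.values, values, atol=1e-6)  # float32
        assert back.grid == grid

    def test_size_mismatch_rejected(self, tmp_path):
        grid = WavelengthGrid(np.array([450.0, 550.0, 650.0]))
        cube = Cube(grid, np.zeros((2, 2, 3)))
        write_envi_cube(cube, tmp_path / "cube.bsq")
        hdr = (tmp_path / "cube.hdr").read_text().replace("bands = 3", "bands = 4")
        (tmp_path / "cube.hdr").write_text(
            hdr.replace("wavelength = { 450.000000, 550.000000, 650.000000 }",
                        "wavelength = { 450, 550, 650, 750 }"))
        with pytest.raises(FormatError):
            read_envi_cube(tmp_path / "cube.hdr")

    def test_uint16_reflectance_scale(self, tmp_path):
        # hand-written 1x1x2 cube: counts 5000 and 10000 at scale 10000
        np.array([5000, 10000], dtype=np.uint16).tofile(tmp_path / "u.bsq")
        (tmp_path / "u.hdr").write_text(
            "ENVI\nsamples = 1\nlines = 1\nbands = 2\ndata type = 12\n"
            "interleave = bsq\nreflectance scale factor = 10000\n"
            "wavelength = { 500, 600 }\n"
        )
        cube = read_envi_cube(tmp_path / "u.hdr")
        np.testing.assert_allclose(cube.values[0, 0], [0.5, 1.0])

    def test_bil_interleave(self, tmp_path):
        # BIL layout: row-major (lines, bands, samples)
        values = np.arange(2 * 2 * 3, dtype=np.float64).reshape(2, 2, 3)
        bil = values.transpose(0, 2, 1)  # rows, bands, cols
        bil.tofile(tmp_path / "c.bil")
        (tmp_path / "c.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 3\ndata type = 5\n"
            "interleave = bil\nwavelength = { 500, 600, 700 }\n"
        )
        with pytest.warns(UserWarning):  # values 0..11 exceed reflectance range
            cube = read_envi_cube(tmp_path / "c.hdr")
        np.testing.assert_array_equal(cube.values, values)

    def test_missing_wavelengths_rejected(self, tmp_path):
        np.zeros(4, dtype=np.float32).tofile(tmp_path / "c.bsq")
        (tmp_path / "c.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 1\ndata type = 4\ninterleave = bsq\n"
        )
        with pytest.raises(FormatError):
            read_envi_cube(tmp_path / "c.hdr")


class TestClipAndResample:
    def test_clip_to_working_range(self):
        grid = WavelengthGrid(np.array([350.0, 500.0, 1100.0, 1150.0]))
        spectra = SpectraSet(grid, np.array([[0.1, 0.2, 0.3, 0.4]]))
        clipped = clip_to_range(spectra, 406.0, 1100.0)
        np.testing.assert_array_equal(clipped.grid.wavelengths_nm, [500.0, 1100.0])
        np.testing.assert_array_equal(clipped.values, [[0.2, 0.3]])

    def test_clip_identity_and_idempotence(self):
        grid = WavelengthGrid(np.array([400.0, 500.0, 600.0]))
        spectra = SpectraSet(grid, np.random.default_rng(0).uniform(0, 1, (3, 3)))
        once = clip_to_range(spectra, 400.0, 600.0)
        twice = clip_to_range(once, 400.0, 600.0)
        np.testing.assert_array_equal(once.values, spectra.values)
        np.testing.assert_array_equal(twice.values, once.values)

    def test_clip_to_empty_range_rejected(self):
        grid = WavelengthGrid(np.array([400.0, 500.0]))
        spectra = SpectraSet(grid, np.zeros((1, 2)))
        with pytest.raises(DegenerateGridError):
            clip_to_range(spectra, 2000.0, 3000.0)

    def test_resample_identity(self):
        grid = WavelengthGrid(np.linspace(400, 900, 11))
        spectra = SpectraSet(grid, np.random.default_rng(1).uniform(0, 1, (2, 11)))
        out = resample_to_grid(spectra, grid)
        np.testing.assert_array_equal(out.values, spectra.values)

    def test_nearest_band_with_tie_to_lower(self):
        src = WavelengthGrid(np.array([400.0, 410.0, 420.0]))
        spectra = SpectraSet(src, np.array([[0.1, 0.2, 0.3]]))
        out = resample_to_grid(spectra, WavelengthGrid(np.array([411.0])))
        assert out.values[0, 0] == 0.2  # 410 is nearest
        tie = resample_to_grid(spectra, WavelengthGrid(np.array([415.0])))
        assert tie.values[0, 0] == 0.2  # equidistant: lower wavelength wins

    def test_decimation_equals_index_arithmetic(self):
        src = WavelengthGrid(np.arange(400.0, 500.0, 1.0))
        values = np.random.default_rng(2).uniform(0, 1, (3, 100))
        spectra = SpectraSet(src, values)
        target = WavelengthGrid(np.arange(400.0, 500.0, 5.0))
        out = resample_to_grid(spectra, target)
        np.testing.assert_array_equal(out.values, values[:, ::5])

    def test_coverage_gap_rejected(self):
        src = WavelengthGrid(np.array([400.0, 500.0]))
        spectra = SpectraSet(src, np.zeros((1, 2)))
        with pytest.raises(CoverageError):
            resample_to_grid(spectra, WavelengthGrid(np.array([450.0])), max_gap_nm=10.0)
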