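import numpy as np
import pytest

from beanspec.hypercube import Hypercube
from beanspec.segmentation import (
    ObjectMap,
    SpectralTable,
    extract_mean_spectra,
    label_objects,
    threshold_mask,
)

WL = np.linspace(980.0, 2500.0, 8)


def absorbance_cube(arr):
    return Hypercube(arr, WL, signal="absorbance")


class TestThresholdMask:
    def make(self, r1186):
        arr = np.full((2, 2, WL.size), 0.5)
        from beanspec.hypercube import band_index

        arr[0, 0, band_index(WL, 1186.0)] = -np.log10(r1186) if r1186 > 0 else 6.0
        return absorbance_cube(arr)

    def test_bright_pixel_is_foreground(self):
        mask = threshold_mask(self.make(0.5))  # A = 0.301
        assert mask[0, 0]

    def test_dark_pixel_is_background(self):
        mask = threshold_mask(self.make(0.05))  # A = 1.301
        assert not mask[0, 0]

    def test_boundary_is_strict(self):
        cube = self.make(0.1)  # A = 1.0 exactly
        assert not threshold_mask(cube)[0, 0]

    def test_requires_absorbance(self):
        cube = Hypercube(np.full((2, 2, WL.size), 0.5), WL, signal="reflectance")
        with pytest.raises(ValueError):
            threshold_mask(cube)

    def test_wavelength_outside_range(self):
        with pytest.raises(ValueError):
            threshold_mask(self.make(0.5), wavelength_nm=5000.0)


class TestLabelObjects:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:7, 2:7] = True
        mask[10:15, 10:15] = True
        omap = label_objects(mask, min_pixels=10)
        assert omap.n_objects == 2
        # raster order: the upper-left square is object 1
        assert omap.labels[2, 2] == 1 and omap.labels[10, 10] == 2

    def test_connectivity_semantics(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True  # touches only diagonally
        assert label_objects(mask, min_pixels=1, connectivity=8).n_objects == 1
        assert label_objects(mask, min_pixels=1, connectivity=4).n_objects == 2

    def test_small_objects_dropped_and_labels_contiguous(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:3, 1:3] = True       # 4 px, dropped
        mask[6:12, 6:12] = True     # kept
        mask[15:19, 15:19] = True   # kept
        omap = label_objects(mask, min_pixels=10)
        assert omap.n_objects == 2
        assert sorted(np.unique(omap.labels)) == [0, 1, 2]

    def test_empty_mask(self):
        omap = label_objects(np.zeros((5, 5), dtype=bool))
        assert omap.n_objects == 0

    def test_rotation_invariance_of_sizes(self, noiseless_absorbance):
        cube, _ = noiseless_absorbance
        mask = threshold_mask(cube)
        a = label_objects(mask)
        b = label_objects(mask[::-1, ::-1])
        assert a.n_objects == b.n_objects
        assert sorted(a.pixel_counts) == sorted(b.pixel_counts)


class TestExtractMeanSpectra:
    def test_uniform_object_returns_its_spectrum(self):
        arr = np.zeros((4, 4, WL.size))
        s = np.linspace(0.2, 0.8, WL.size)
        arr[1:3, 1:3] = s
        labels = np.zeros((4, 4), dtype=int)
        labels[1:3, 1:3] = 1
        table = extract_mean_spectra(absorbance_cube(arr), ObjectMap(labels))
        np.testing.assert_allclose(table.X[0], s)

    def test_two_pixel_average(self):
        arr = np.zeros((1, 2, WL.size))
        arr[0, 0] = 0.2
        arr[0, 1] = 0.4
        labels = np.ones((1, 2), dtype=int)
        table = extract_mean_spectra(absorbance_cube(arr), ObjectMap(labels))
        np.testing.assert_allclose(table.X[0], 0.3)

    def test_commutes_with_per_band_affine(self, noiseless_absorbance):
        cube, _ = noiseless_absorbance
        omap = label_objects(threshold_mask(cube))
        gains = np.linspace(0.5, 2.0, cube.n_bands)
        offs = np.linspace(-0.1, 0.1, cube.n_bands)
        t1 = extract_mean_spectra(cube, omap)
        shifted = Hypercube(cube.cube * gains + offs, cube.wavelengths,
                            signal="absorbance")
        t2 = extract_mean_spectra(shifted, omap)
        np.testing.assert_allclose(t1.X * gains + offs, t2.X, atol=1e-12)

    def test_noiseless_bean_mean_equals_mixture_at_mean_composition(
        self, lib64, noiseless_absorbance
    ):
        """Mixing is linear, so the mean spectrum is the mixture at the
        bean-average composition."""
        cube, truth = noiseless_absorbance
        import beanspec.synthetic as syn
        from conftest import clean_scene_spec

        spec = clean_scene_spec()
        comp = syn._draw_compositions(np.random.default_rng(spec.seed), spec)
        table = extract_mean_spectra(cube, ObjectMap(truth.object_map))
        for k in range(truth.n_beans):
            sel = truth.object_map == k + 1
            m = truth.moisture_map[sel] / 100
            f = truth.fat_dmb_map[sel] / 100 * (1 - m)
            c = comp.loc[k, "marker_frac"]
            expected = lib64.mixture(
                {"water": m.mean(), "lipid": f.mean(), "marker": c,
                 "matrix": 1 - m.mean() - f.mean() - c}
            )
            assert np.abs(table.X[k] - expected).max() < 1e-10

    def test_shape_mismatch_rejected(self):
        arr = np.zeros((4, 4, WL.size))
        with pytest.raises(ValueError):
            extract_mean_spectra(absorbance_cube(arr), ObjectMap(np.zeros((3, 3), dtype=int)))


class TestSpectralTableIO:
    def test_csv_roundtrip(self, tmp_path, lib256):
        from beanspec.synthetic import generate_calibration_table

        table = generate_calibration_table(8, lib=lib256, seed=4)
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = SpectralTable.from_csv(path)
        np.testing.assert_allclose(back.X, table.X, rtol=1e-12)
        np.testing.assert_allclose(back.y("moisture_pct"), table.y("moisture_pct"))
        assert list(back.references["species"]) == list(table.references["species"])
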