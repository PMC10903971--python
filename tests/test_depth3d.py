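"""Depth-map cleaning pipeline and 3D feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from topmorph import (
    CalibrationConfig,
    DepthMap,
    InstanceMask,
    PhantomSpec,
    apply_mask,
    depth_to_heatmap,
    export_surface_grid,
    extract_3d_features,
    fill_missing,
    gaussian_smooth,
    generate_phantom,
    load_depth_csv,
    to_height_field,
    write_depth_csv,
)
from topmorph.depth3d import DepthParseError, HeightField, load_surface_grid

from conftest import rect_mask


def full_mask(shape, value=True):
    return InstanceMask(np.full(shape, value, dtype=bool))


class TestDepthCsvIO:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("2.5,2.5\n2.5,2.1\n")
        d = load_depth_csv(p)
        assert (d.rows, d.cols) == (2, 2)
        assert d.values[1, 1] == 2.1

    def test_header_row_autodetected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("c0,c1\n1.0,2.0\n")
        d = load_depth_csv(p)
        assert d.shape == (1, 2)

    def test_ragged_rows_rejected_with_row_number(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("1,2,3\n1,2,3,4\n")
        with pytest.raises(DepthParseError, match="row 1"):
            load_depth_csv(p)

    def test_non_numeric_cell_named(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("1,2\n1,x\n")
        with pytest.raises(DepthParseError, match=r"row 1, col 1"):
            load_depth_csv(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("")
        with pytest.raises(DepthParseError, match="empty"):
            load_depth_csv(p)

    def test_negative_depth_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("1,2\n-1,0\n")
        with pytest.raises(ValueError, match="negative"):
            load_depth_csv(p)

    def test_phantom_roundtrip(self, tmp_path):
        from topmorph import AnimalSpec

        spec = PhantomSpec(rows=120, cols=160, seed=5,
                           animals=(AnimalSpec(center_row=60, center_col=80,
                                               a=0.45, b=0.22, c=0.35),))
        depth, _, _ = generate_phantom(spec)
        p = tmp_path / "d.csv"
        write_depth_csv(depth, p)
        back = load_depth_csv(p)
        assert np.abs(back.values - depth.values).max() < 1e-9


class TestHeatmap:
    def test_constant_grid_uniform_low_end(self):
        img = depth_to_heatmap(DepthMap(np.full((4, 6), 2.5)), "viridis")
        assert img.shape == (4, 6, 3) and img.dtype == np.uint8
        assert (img == img[0, 0]).all()
        import matplotlib

        low = np.round(np.array(matplotlib.colormaps["viridis"](0.0)[:3]) * 255)
        assert np.array_equal(img[0, 0], low.astype(np.uint8))

    def test_min_max_map_to_colormap_endpoints(self):
        import matplotlib

        grid = np.array([[1.0, 3.0], [2.0, 2.5]])
        img = depth_to_heatmap(DepthMap(grid), "viridis")
        cmap = matplotlib.colormaps["viridis"]
        lo = np.round(np.array(cmap(0.0)[:3]) * 255).astype(np.uint8)
        hi = np.round(np.array(cmap(1.0)[:3]) * 255).astype(np.uint8)
        assert np.array_equal(img[0, 0], lo)
        assert np.array_equal(img[0, 1], hi)

    def test_monotone_gradient_is_monotone_in_gray(self):
        grid = np.linspace(1.0, 2.0, 16)[None, :]
        img = depth_to_heatmap(DepthMap(grid), "gray")
        levels = img[0, :, 0].astype(int)
        assert (np.diff(levels) >= 0).all() and levels[-1] > levels[0]

    def test_unknown_colormap_lists_alternatives(self):
        with pytest.raises(ValueError, match="unknown colormap"):
            depth_to_heatmap(DepthMap(np.ones((2, 2))), "no_such_map")


class TestApplyMask:
    def test_identity_and_annihilation(self):
        d = DepthMap(np.arange(6, dtype=float).reshape(2, 3) + 1)
        assert np.array_equal(apply_mask(d, full_mask((2, 3))).values, d.values)
        assert not apply_mask(d, full_mask((2, 3), False)).values.any()

    def test_elementwise_oracle(self, rng):
        d = DepthMap(rng.uniform(0.5, 3.0, size=(15, 17)))
        mask = InstanceMask(rng.random((15, 17)) < 0.4)
        out = apply_mask(d, mask)
        for i, j in zip(*np.nonzero(rng.random((15, 17)) < 0.2)):
            assert out.values[i, j] == d.values[i, j] * mask.pixels[i, j]

    def test_shape_mismatch_reports_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(2, 3\).*\(3, 2\)"):
            apply_mask(DepthMap(np.ones((2, 3))), full_mask((3, 2)))


class TestFillMissing:
    def test_mean_fill(self):
        out = fill_missing(DepthMap(np.array([[2.0, 0.0], [4.0, 0.0]])))
        assert np.array_equal(out.values, [[2.0, 3.0], [4.0, 3.0]])

    def test_no_zero_identity(self):
        v = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(fill_missing(DepthMap(v)).values, v)

    def test_dropout_fill_matches_independent_mean(self, rng):
        v = rng.uniform(1.0, 3.0, size=(40, 50))
        drop = rng.random(v.shape) < 0.05
        v[drop] = 0.0
        out = fill_missing(DepthMap(v))
        expected_mean = v[~drop].sum() / (~drop).sum()
        assert np.allclose(out.values[drop], expected_mean)
        assert np.array_equal(out.values[~drop], v[~drop])
        assert (out.values != 0).all()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fill_missing(DepthMap(np.zeros((3, 3))))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        v = r.uniform(0.5, 3.0, size=(10, 12))
        v[r.random(v.shape) < 0.3] = 0.0
        if not v.any():
            v[0, 0] = 1.0
        once = fill_missing(DepthMap(v))
        twice = fill_missing(once)
        assert np.array_equal(once.values, twice.values)


class TestGaussianSmooth:
    def test_sigma_zero_is_identity(self, rng):
        v = rng.uniform(0, 3, size=(9, 9))
        assert np.array_equal(gaussian_smooth(DepthMap(v), 0.0).values, v)

    def test_constant_grid_is_fixed_point(self):
        v = np.full((20, 20), 2.5)
        out = gaussian_smooth(DepthMap(v), 3.0)
        assert np.abs(out.values - 2.5).max() < 1e-9

    def test_impulse_response_normalized_symmetric(self):
        v = np.zeros((41, 41))
        v[20, 20] = 1.0
        out = gaussian_smooth(DepthMap(v), 1.0).values
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(out, out.T)
        assert np.allclose(out, out[::-1, :])
        # center row matches the truncated, normalized Gaussian kernel
        radius = int(4.0 * 1.0 + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * x**2)
        k /= k.sum()
        assert np.allclose(out[20, 20 - radius:20 + radius + 1], k * k[radius],
                           atol=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(DepthMap(np.ones((3, 3))), -1.0)


class TestHeightField:
    def test_flat_floor_is_zero_height(self):
        d = DepthMap(np.full((10, 10), 2.5))
        cfg = CalibrationConfig(gaussian_sigma=0.0)
        f = to_height_field(d, cfg, full_mask((10, 10)))
        assert np.abs(f.heights).max() < 1e-12

    def test_height_is_camera_minus_depth(self):
        v = np.full((5, 5), 2.5)
        v[2, 2] = 2.1
        f = to_height_field(DepthMap(v), CalibrationConfig(gaussian_sigma=0.0),
                            full_mask((5, 5)))
        assert f.heights[2, 2] == pytest.approx(0.4)

    def test_phantom_apex_height(self):
        spec = PhantomSpec(noise_sd=0.0, dropout_rate=0.0, seed=0)
        depth, masks, _ = generate_phantom(spec)
        cfg = CalibrationConfig(ppm=100, gaussian_sigma=0.0)
        f = to_height_field(depth, cfg, masks.best())
        assert f.heights.max() == pytest.approx(0.4, abs=1e-6)

    def test_mismatched_roi_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            to_height_field(DepthMap(np.ones((3, 3))), CalibrationConfig(),
                            full_mask((4, 4)))


class TestExtract3DFeatures:
    @staticmethod
    def _flat_mound(ppm=1.0):
        v = np.full((20, 20), 2.5)
        px = np.zeros((20, 20), dtype=bool)
        px[5:15, 5:15] = True  # 100-pixel square mound
        v[px] = 2.2  # height 0.3
        mask = InstanceMask(px)
        cfg = CalibrationConfig(ppm=ppm, gaussian_sigma=0.0)
        field = to_height_field(DepthMap(v), cfg, mask)
        return field, mask, cfg

    def test_uniform_mound(self):
        field, mask, cfg = self._flat_mound(ppm=1.0)
        rec = extract_3d_features(field, mask, cfg)
        assert rec.height_average == pytest.approx(0.3)
        assert rec.height_centroid == pytest.approx(0.3)
        assert rec.volume == pytest.approx(30.0)
        assert rec.has_3d

    def test_volume_scales_with_ppm_squared_heights_do_not(self):
        field, mask, cfg = self._flat_mound(ppm=10.0)
        rec = extract_3d_features(field, mask, cfg)
        assert rec.volume == pytest.approx(0.30)
        assert rec.height_average == pytest.approx(0.3)
        assert rec.height_centroid == pytest.approx(0.3)

    def test_half_ellipsoid_closed_form_recovery(self):
        spec = PhantomSpec(noise_sd=0.0, dropout_rate=0.0, seed=0)
        depth, masks, truth = generate_phantom(spec)
        cfg = CalibrationConfig(ppm=100, gaussian_sigma=0.0)
        mask = masks.best()
        rec = extract_3d_features(to_height_field(depth, cfg, mask), mask, cfg)
        t = truth.animals[0]
        assert rec.height_centroid == pytest.approx(t.height_centroid, rel=0.01)
        assert rec.height_average == pytest.approx(t.height_average, rel=0.02)
        assert rec.volume == pytest.approx(t.volume, rel=0.02)

    def test_empty_mask_rejected(self):
        field = HeightField(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            extract_3d_features(field, full_mask((4, 4), False),
                                CalibrationConfig())

    def test_calibration_linearity_exact(self):
        spec = PhantomSpec(noise_sd=0.0, dropout_rate=0.0, seed=0)
        depth, masks, _ = generate_phantom(spec)
        mask = masks.best()
        recs = {}
        for ppm in (1.0, 2.0):
            cfg = CalibrationConfig(ppm=ppm, gaussian_sigma=1.0)
            recs[ppm] = extract_3d_features(to_height_field(depth, cfg, mask),
                                            mask, cfg)
        assert recs[2.0].height_average == recs[1.0].height_average
        assert recs[2.0].height_centroid == recs[1.0].height_centroid
        assert recs[2.0].volume == recs[1.0].volume / 4.0
        assert recs[2.0].area == recs[1.0].area / 4.0
        assert recs[2.0].dorsal_length == recs[1.0].dorsal_length / 2.0


class TestPipelineProperties:
    def test_roi_variance_nonincreasing_in_sigma(self):
        spec = PhantomSpec(seed=9)  # defaults: 1 cm noise, 2% dropout
        depth, masks, _ = generate_phantom(spec)
        mask = masks.best()
        variances = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            cfg = CalibrationConfig(ppm=100, gaussian_sigma=sigma)
            f = to_height_field(depth, cfg, mask)
            variances.append(f.heights[mask.pixels].var())
        assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))

    def test_volume_approximately_conserved_under_smoothing(self):
        spec = PhantomSpec(noise_sd=0.0, dropout_rate=0.0, seed=2)
        depth, masks, _ = generate_phantom(spec)
        mask = masks.best()
        vols = {}
        for sigma in (0.0, 2.0):
            cfg = CalibrationConfig(ppm=100, gaussian_sigma=sigma)
            f = to_height_field(depth, cfg, mask)
            vols[sigma] = extract_3d_features(f, mask, cfg).volume
        assert vols[2.0] == pytest.approx(vols[0.0], rel=0.05)


class TestSurfaceExport:
    def test_roundtrip_lossless(self, tmp_path):
        spec = PhantomSpec(seed=4)
        depth, masks, _ = generate_phantom(spec)
        cfg = CalibrationConfig(ppm=100)
        f = to_height_field(depth, cfg, masks.best())
        p = tmp_path / "surface.csv"
        export_surface_grid(f, p)
        back = load_surface_grid(p)
        assert np.abs(back - f.heights).max() < 1e-9

    def test_single_cell_grid(self, tmp_path):
        f = HeightField(np.array([[0.25]]), np.array([[True]]))
        p = tmp_path / "one.csv"
        export_surface_grid(f, p)
        assert load_surface_grid(p).shape == (1, 1)

    def test_header_flag(self, tmp_path):
        f = HeightField(np.zeros((2, 3)), np.ones((2, 3), dtype=bool))
        p = tmp_path / "h.csv"
        export_surface_grid(f, p, header=True)
        first = p.read_text().splitlines()[0]
        assert first == "c0,c1,c2"
        export_surface_grid(f, p, header=False)
        first = p.read_text().splitlines()[0]
        assert first.split(",")[0] == "0"
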