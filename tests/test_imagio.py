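import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echorange.errors import (
    DegenerateImageError,
    EmptyMaskError,
    UnsupportedFormatError,
)
from echorange.imagio import (
    RoiPolygon,
    extract_sample,
    load_roi,
    normalize_image,
    rasterize_roi,
    read_image,
    save_roi,
    to_grayscale,
    write_image,
)


class TestToGrayscale:
    def test_single_channel_passthrough(self):
        img = np.arange(12, dtype=np.uint8).reshape(3, 4)
        np.testing.assert_array_equal(to_grayscale(img), img)

    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((100, 100, 100), 100),   # equal channels forced
            ((255, 0, 0), 76),        # round(0.299*255)
            ((0, 255, 0), 150),       # round(0.587*255)
            ((0, 0, 255), 29),        # round(0.114*255)
        ],
    )
    def test_rec601_luma(self, rgb, expected):
        raster = np.full((2, 2, 3), rgb, dtype=np.uint8)
        assert to_grayscale(raster)[0, 0] == expected

    def test_alpha_ignored(self):
        raster = np.zeros((1, 1, 4), dtype=np.uint8)
        raster[0, 0] = (255, 0, 0, 7)
        assert to_grayscale(raster)[0, 0] == 76

    def test_rejects_non_8bit(self):
        with pytest.raises(UnsupportedFormatError):
            to_grayscale(np.zeros((2, 2), dtype=np.uint16))


class TestNormalize:
    def test_affine_endpoints_and_midpoint(self):
        img = np.array([[10, 110, 210]], dtype=np.uint8)
        # midpoint 127.5 rounds away from zero to 128
        np.testing.assert_array_equal(
            normalize_image(img, 255), np.array([[0, 128, 255]])
        )

    def test_full_span_unchanged(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        img[0, 0], img[0, 1] = 0, 255
        np.testing.assert_array_equal(normalize_image(img, 255), img)

    def test_degenerate_image_raises(self):
        with pytest.raises(DegenerateImageError):
            normalize_image(np.full((3, 3), 5, dtype=np.uint8), 255)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_order_preserving(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        if img.min() == img.max():
            img[0, 0] = (int(img[0, 1]) + 1) % 256
        once = normalize_image(img, 255)
        twice = normalize_image(once, 255)
        np.testing.assert_array_equal(once, twice)
        # weak-order preservation
        flat, nflat = img.ravel().astype(int), once.ravel().astype(int)
        order = np.argsort(flat, kind="stable")
        assert np.all(np.diff(nflat[order]) >= 0)

    def test_global_extremes_override(self):
        img = np.array([[50, 100]], dtype=np.uint8)
        out = normalize_image(img, 255, f_min=0, f_max=200)
        np.testing.assert_array_equal(out, [[64, 128]])


class TestRasterizeRoi:
    def test_unit_square_covers_four_pixels(self):
        poly = RoiPolygon(((-0.5, -0.5), (1.5, -0.5), (1.5, 1.5), (-0.5, 1.5)))
        mask = rasterize_roi(poly, 4, 4)
        expected = np.zeros((4, 4), dtype=bool)
        expected[:2, :2] = True
        np.testing.assert_array_equal(mask, expected)

    def test_degenerate_polygon_raises(self):
        poly = RoiPolygon(((0, 0), (1, 1), (2, 2)))
        with pytest.raises(EmptyMaskError):
            rasterize_roi(poly, 4, 4)

    def test_covering_polygon_is_all_true(self):
        poly = RoiPolygon(((-1, -1), (10, -1), (10, 10), (-1, 10)))
        assert rasterize_roi(poly, 5, 5).all()

    def test_outside_polygon_raises(self):
        poly = RoiPolygon(((100, 100), (110, 100), (110, 110)))
        with pytest.raises(EmptyMaskError):
            rasterize_roi(poly, 5, 5)

    @pytest.mark.parametrize("n", [8, 32, 128])
    def test_mask_area_converges_to_square_area(self, n):
        # square with 60% linear extent of an n x n image
        a, b = 0.2 * n, 0.8 * n
        poly = RoiPolygon(((a, a), (b, a), (b, b), (a, b)))
        area = rasterize_roi(poly, n, n).sum()
        geometric = (b - a) ** 2
        assert abs(area - geometric) / geometric < 4.0 / (0.6 * n)

    def test_abutting_polygons_partition_pixels(self):
        # half-open rule: shared vertical edge claims each pixel exactly once
        left = RoiPolygon(((-0.5, -0.5), (2.0, -0.5), (2.0, 3.5), (-0.5, 3.5)))
        right = RoiPolygon(((2.0, -0.5), (4.5, -0.5), (4.5, 3.5), (2.0, 3.5)))
        ml = rasterize_roi(left, 5, 4)
        mr = rasterize_roi(right, 5, 4)
        assert not (ml & mr).any()
        assert (ml | mr)[:, :5].sum() == 20


class TestExtractSample:
    def test_row_major_order(self):
        img = np.array([[1, 2], [3, 4]])
        mask = np.ones((2, 2), dtype=bool)
        np.testing.assert_array_equal(extract_sample(img, mask).values, [1, 2, 3, 4])

    def test_diagonal_mask(self):
        img = np.array([[1, 2], [3, 4]])
        mask = np.eye(2, dtype=bool)
        np.testing.assert_array_equal(extract_sample(img, mask).values, [1, 4])

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_sample(np.ones((2, 2)), np.zeros((2, 2), dtype=bool))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sample_length_equals_mask_popcount(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(6, 7))
        mask = rng.random((6, 7)) < 0.5
        if not mask.any():
            mask[0, 0] = True
        assert extract_sample(img, mask).n == int(mask.sum())


class TestFileRoundTrips:
    def test_png_image_round_trip(self, tmp_path):
        img = np.random.default_rng(1).integers(0, 256, (9, 7)).astype(np.uint8)
        path = tmp_path / "img.png"
        write_image(path, img)
        np.testing.assert_array_equal(read_image(path), img)

    def test_rgb_png_is_converted(self, tmp_path):
        rgb = np.zeros((3, 3, 3), dtype=np.uint8)
        rgb[..., 0] = 255
        path = tmp_path / "rgb.png"
        write_image(path, rgb)
        assert read_image(path)[0, 0] == 76

    def test_roi_json_round_trip(self, tmp_path):
        poly = RoiPolygon(((0.5, 1.5), (10, 2), (5, 9)))
        path = tmp_path / "roi.json"
        save_roi(path, poly)
        assert load_roi(path) == poly
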