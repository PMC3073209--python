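"""Slide opening, region reads, tile planning, and grayscale conversion."""

import numpy as np
import pytest
import tifffile
import imageio.v3 as iio
from hypothesis import given, settings, strategies as st

from slidefocus import open_slide, plan_tiles, read_region, to_grayscale
from slidefocus.errors import RegionRangeError, SlideFormatError, SlideValidationError
from slidefocus.wsi_io import SlideSource


class TestOpenSlide:
    def test_flat_tiff_dimensions_round_trip(self, tmp_path):
        arr = np.zeros((768, 1024, 3), dtype=np.uint8)
        path = tmp_path / "flat.tiff"
        tifffile.imwrite(path, arr, photometric="rgb")
        src = open_slide(path)
        assert (src.width_px, src.height_px) == (1024, 768)
        assert src.source_kind == "flat_tiff"
        assert src.n_channels == 3

    def test_pyramidal_tiff_selects_largest_plane(self, tmp_path):
        path = tmp_path / "pyramid.tiff"
        with tifffile.TiffWriter(path) as tw:
            # smaller plane first: level 0 must be picked by size, not order
            tw.write(np.zeros((512, 512, 3), dtype=np.uint8), photometric="rgb")
            tw.write(np.full((2048, 2048, 3), 9, dtype=np.uint8), photometric="rgb")
        src = open_slide(path)
        assert src.source_kind == "pyramidal_tiff"
        assert (src.width_px, src.height_px) == (2048, 2048)
        assert src.level0()[0, 0, 0] == 9

    def test_png(self, tmp_path):
        arr = np.full((60, 80, 3), 200, dtype=np.uint8)
        path = tmp_path / "x.png"
        iio.imwrite(path, arr)
        src = open_slide(path)
        assert (src.width_px, src.height_px) == (80, 60)

    def test_tile_directory(self, tmp_path):
        root = tmp_path / "tiles"
        (root / "0").mkdir(parents=True)
        rng = np.random.default_rng(3)
        full = rng.integers(0, 256, size=(100, 150, 3), dtype=np.uint8)
        # 2 cols x 2 rows, ragged edges
        for c, (x0, x1) in enumerate([(0, 100), (100, 150)]):
            for r, (y0, y1) in enumerate([(0, 64), (64, 100)]):
                iio.imwrite(root / "0" / f"{c}_{r}.png", full[y0:y1, x0:x1])
        src = open_slide(root)
        assert (src.width_px, src.height_px) == (150, 100)
        np.testing.assert_array_equal(src.level0(), full)

    def test_truncated_file_is_format_error(self, tmp_path):
        path = tmp_path / "broken.tiff"
        path.write_bytes(b"II*\x00garbage")
        with pytest.raises(SlideFormatError):
            open_slide(path)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(SlideFormatError, match="nowhere.tiff"):
            open_slide(tmp_path / "nowhere.tiff")

    def test_unsupported_suffix(self, tmp_path):
        path = tmp_path / "x.jpg"
        path.write_bytes(b"\xff\xd8\xff")
        with pytest.raises(SlideFormatError):
            open_slide(path)

    def test_sixteen_bit_rejected(self, tmp_path):
        path = tmp_path / "deep.tiff"
        tifffile.imwrite(path, np.zeros((64, 64, 3), dtype=np.uint16), photometric="rgb")
        src = open_slide(path)
        with pytest.raises(SlideFormatError, match="8-bit"):
            src.level0()


class TestReadRegion:
    def test_single_pixel_of_white_fixture(self, tmp_path):
        path = tmp_path / "white.png"
        iio.imwrite(path, np.full((16, 16, 3), 255, dtype=np.uint8))
        region = read_region(open_slide(path), 0, 0, 1, 1)
        assert region.pixels.shape == (1, 1, 3)
        assert tuple(region.pixels[0, 0]) == (255, 255, 255)

    def test_reads_are_deterministic(self, small_rgb_tiff):
        path, _ = small_rgb_tiff
        src = open_slide(path)
        a = read_region(src, 10, 20, 50, 40)
        b = read_region(src, 10, 20, 50, 40)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_matches_whole_image_crop(self, small_rgb_tiff):
        path, arr = small_rgb_tiff
        src = open_slide(path)
        region = read_region(src, 30, 10, 64, 64)
        np.testing.assert_array_equal(region.pixels, arr[10:74, 30:94])
        assert not region.clipped

    def test_edge_overlap_is_clipped_and_flagged(self, small_rgb_tiff):
        path, arr = small_rgb_tiff
        src = open_slide(path)  # 256 wide
        region = read_region(src, 240, 0, 64, 32)
        assert region.clipped
        assert region.width_px == 16
        np.testing.assert_array_equal(region.pixels, arr[0:32, 240:256])

    def test_fully_outside_raises(self, small_rgb_tiff):
        path, _ = small_rgb_tiff
        src = open_slide(path)
        with pytest.raises(RegionRangeError):
            read_region(src, 10_000, 0, 10, 10)

    def test_zero_size_rejected(self, small_rgb_tiff):
        src = open_slide(small_rgb_tiff[0])
        with pytest.raises(SlideValidationError):
            read_region(src, 0, 0, 0, 5)


def _fake_slide(w, h):
    return SlideSource(path="<mem>", width_px=w, height_px=h, n_channels=3,
                       source_kind="flat_tiff")


class TestPlanTiles:
    @pytest.mark.parametrize("w,h,tile,sub,expect_tiles,expect_grid", [
        (4096, 2048, 2048, 128, 2, (32, 16)),
        (4100, 2048, 2048, 128, 2, (32, 16)),   # 4-px margin unassessed
        (1000, 1000, 2048, 128, 1, (7, 7)),     # single sub-maximal tile
    ])
    def test_examples(self, w, h, tile, sub, expect_tiles, expect_grid):
        tasks = plan_tiles(_fake_slide(w, h), tile, sub)
        assert len(tasks) == expect_tiles
        gw, gh = expect_grid
        covered = sum(t.width_px * t.height_px for t in tasks)
        assert covered == gw * sub * gh * sub
        for t in tasks:
            assert t.x_px % sub == 0 and t.y_px % sub == 0
            assert t.width_px % sub == 0 and t.height_px % sub == 0

    def test_row_major_order_and_disjoint(self):
        tasks = plan_tiles(_fake_slide(1000, 900), 256, 64)
        keys = [(t.y_px, t.x_px) for t in tasks]
        assert keys == sorted(keys)
        assert [t.tile_id for t in tasks] == list(range(len(tasks)))

    def test_slide_smaller_than_subtile_rejected(self):
        with pytest.raises(SlideValidationError):
            plan_tiles(_fake_slide(100, 100), 2048, 128)

    def test_tile_not_multiple_of_subtile_rejected(self):
        with pytest.raises(SlideValidationError):
            plan_tiles(_fake_slide(1000, 1000), 2000, 128)

    @settings(max_examples=40, deadline=None)
    @given(w=st.integers(128, 5000), h=st.integers(128, 5000),
           tile_mult=st.integers(1, 20))
    def test_partition_property(self, w, h, tile_mult):
        """Sub-tile lattice cells across all tiles: no gaps, no duplicates."""
        sub = 128
        tasks = plan_tiles(_fake_slide(w, h), tile_mult * sub, sub)
        cells = []
        for t in tasks:
            for gy in range(t.grid_y0, t.grid_y0 + t.height_px // sub):
                for gx in range(t.grid_x0, t.grid_x0 + t.width_px // sub):
                    cells.append((gx, gy))
        gw, gh = w // sub, h // sub
        assert len(cells) == len(set(cells)) == gw * gh
        assert set(cells) == {(x, y) for x in range(gw) for y in range(gh)}


class TestToGrayscale:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 255, 255), 255.0),
        ((255, 0, 0), 76.245),
        ((0, 0, 0), 0.0),
    ])
    def test_luma_weights(self, rgb, expected):
        pixel = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        assert to_grayscale(pixel)[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_constant_region_stays_constant(self):
        block = np.full((8, 8, 3), 77, dtype=np.uint8)
        gray = to_grayscale(block)
        assert gray.dtype == np.float64
        assert np.ptp(gray) == 0.0

    def test_requires_three_channels(self):
        with pytest.raises(SlideValidationError):
            to_grayscale(np.zeros((8, 8), dtype=np.uint8))
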