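import numpy as np
import pytest
import tifffile

from slidefocus import Region, SlideSpec, generate_slide, open_slide


@pytest.fixture(scope="session")
def mixed_spec():
    """1024x1024 slide: 4 sharp-tissue columns, 2 blurred, 2 background."""
    return SlideSpec(1024, 1024, seed=7, regions=(
        Region(0, 0, 4, 8, "tissue", 0.0),
        Region(4, 0, 2, 8, "tissue", 3.0),
        Region(6, 0, 2, 8, "background", 0.0),
    ))


@pytest.fixture(scope="session")
def mixed_slide(mixed_spec, tmp_path_factory):
    """The mixed slide written to TIFF, plus its in-memory raster and truth."""
    path = tmp_path_factory.mktemp("slides") / "mixed.tiff"
    raster, truth = generate_slide(mixed_spec, out_tiff=path)
    return open_slide(path), raster, truth


@pytest.fixture(scope="session")
def small_rgb_tiff(tmp_path_factory):
    """256x192 deterministic random RGB flat TIFF with its raster."""
    rng = np.random.default_rng(42)
    arr = rng.integers(0, 256, size=(192, 256, 3), dtype=np.uint8)
    path = tmp_path_factory.mktemp("fixtures") / "small.tiff"
    tifffile.imwrite(path, arr, photometric="rgb")
    return path, arr
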