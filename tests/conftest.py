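import numpy as np
import pytest

from nucleoquant import classify, segment, synthdata


@pytest.fixture(scope="session")
def small_tile():
    """A modest tile reused across modules: 300x300 um at 0.5 um/px."""
    spec = synthdata.TileSpec(width_px=600, height_px=600, n_cells=70, seed=3)
    rgb, truth = synthdata.make_tile(spec)
    return spec, rgb, truth


@pytest.fixture(scope="session")
def small_tile_segmentation(small_tile):
    _, rgb, _ = small_tile
    params = segment.SegmentationParams()
    instances, mask = segment.segment_tile(rgb, params)
    return params, instances, mask


@pytest.fixture(scope="session")
def small_tile_cells(small_tile):
    """Ground-truth-mask classification of the shared tile."""
    spec, rgb, truth = small_tile
    return classify.classify_cells(rgb, truth.instance_mask, spec.pixel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
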