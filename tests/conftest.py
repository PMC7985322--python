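"""Shared fixtures: the hand-checkable 10x10 scene and helpers."""

import numpy as np
import pytest

from punctakit.segment import SegmentationResult


@pytest.fixture
def toy_scene():
    """10x10 frame: 96 dilute pixels at 10, a 2x2 condensate at 100, background 0.

    Hand arithmetic: area_dense = 4, mean_dense = 100, mean_dilute = 10,
    total integrated density = 96*10 + 4*100 = 1360,
    fraction = 4*(100-10)/1360 = 360/1360, intensity ratio = 400/1360.
    """
    frame = np.full((10, 10), 10.0)
    frame[4:6, 4:6] = 100.0
    cond = np.zeros((10, 10), dtype=bool)
    cond[4:6, 4:6] = True
    cell = np.ones((10, 10), dtype=bool)
    seg = SegmentationResult(
        condensate_mask=cond, cell_mask=cell, threshold_value=55.0,
        cell_threshold_value=0.0, method="otsu", cell_method="mean",
        min_object_px=1)
    return frame, seg


def random_8bit_image(seed, shape=(64, 64)):
    rng = np.random.default_rng(seed)
    # two-population image so thresholds are non-trivial
    img = rng.normal(80, 25, size=shape)
    bright = rng.random(shape) < 0.1
    img[bright] = rng.normal(190, 20, size=int(bright.sum()))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)
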