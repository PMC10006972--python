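import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from footcheck import (
    SceneParams,
    generate_scene,
    generate_scribbles,
    segment_foot,
    segment_ulcer,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

TS0 = dt.datetime(2023, 1, 2, 9, 0)


def iou(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


@pytest.fixture(scope="session")
def default_scene():
    """Seed-1 default scene: (image, truth)."""
    return generate_scene(SceneParams(seed=1))


@pytest.fixture(scope="session")
def default_scribbles(default_scene):
    _, truth = default_scene
    return generate_scribbles(truth, quality="good")


@pytest.fixture(scope="session")
def default_segmentation(default_scene, default_scribbles):
    """Full two-stage segmentation of the seed-1 scene."""
    image, _ = default_scene
    foot = segment_foot(image, default_scribbles)
    return segment_ulcer(image, foot.foot_mask, default_scribbles)
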