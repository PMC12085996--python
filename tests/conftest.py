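import numpy as np
import pandas as pd
import pytest

import roicell as rc


@pytest.fixture(scope="session")
def small_image_fixture():
    """60 non-touching cells in a 600 px image (ground truth attached)."""
    spec = rc.ImageFixtureSpec(
        n_positive=30, n_negative=30, overlap_allowed=False, seed=11
    )
    return rc.make_roi_image(spec)


@pytest.fixture(scope="session")
def cropped_roi(small_image_fixture):
    return rc.detect_and_crop_roi(rc.RoiImage(pixels=small_image_fixture.image))


@pytest.fixture(scope="session")
def seg_params():
    """Diameter matched to the fixture's ~4 px cell radius after 1 px blur."""
    return rc.SegmentationParams(diameter_px=13.0)


@pytest.fixture(scope="session")
def segmented(cropped_roi, seg_params):
    return rc.segment_cells(cropped_roi, seg_params)


def make_mixture_cells(
    n_neg: int = 250,
    n_pos: int = 250,
    neg=(8.0, 2.0),
    pos=(60.0, 8.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted two-Gaussian green-intensity mixture plus ground-truth labels."""
    rng = np.random.default_rng(seed)
    g = np.concatenate(
        [rng.normal(*neg, size=n_neg), rng.normal(*pos, size=n_pos)]
    )
    cells = pd.DataFrame(
        {
            "label": np.arange(1, n_neg + n_pos + 1),
            "mean_r": rng.normal(30, 5, n_neg + n_pos).clip(0, 255),
            "mean_g": g.clip(0, 255),
            "mean_b": rng.normal(120, 10, n_neg + n_pos).clip(0, 255),
        }
    )
    truth = np.array(["negative"] * n_neg + ["positive"] * n_pos)
    return cells, truth


@pytest.fixture()
def mixture_cells():
    return make_mixture_cells(seed=0)
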