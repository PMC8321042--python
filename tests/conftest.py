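import numpy as np
import pytest

from her2mil import synthetic
from her2mil.tiler import SlideImage


@pytest.fixture(scope="session")
def small_slide_spec():
    """A desk-scale slide: 8x6 grid of 64-px cells, half tissue."""
    return synthetic.SyntheticSlideSpec(
        width_px=512, height_px=384, tile_px=64, tissue_fraction=0.5, seed=3
    )


@pytest.fixture(scope="session")
def default_bags():
    """200 probability bags at the default study conditions (means 0.2/0.8,
    positive-tile rate 0.6, 50 tiles/slide, balanced labels)."""
    return synthetic.generate_probability_bags(synthetic.ProbabilityBagSpec(seed=11))


@pytest.fixture(scope="session")
def cue_slide_cohort():
    """24 training + 12 held-out synthetic slides with a planted positive cue."""
    kwargs = dict(width_px=512, height_px=384, tile_px=64, tissue_fraction=0.6)
    train = synthetic.generate_slide_dataset(
        24, positive_tile_fraction=0.6, seed=101, **kwargs
    )
    test = synthetic.generate_slide_dataset(
        12, positive_tile_fraction=0.6, seed=202, **kwargs
    )
    for j, (img, _) in enumerate(test):
        img.slide_id = f"test_{j:03d}"
    return train, test


def constant_image(value: int, h: int = 128, w: int = 128) -> SlideImage:
    return SlideImage("const", np.full((h, w, 3), value, dtype=np.uint8))
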