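import numpy as np
import pytest

from wsicascade import PyramidConfig, SlideSpec, TilePyramid, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """A 1024x1024 slide with two mid-sized lesions (session-cached)."""
    spec = SlideSpec(
        width=1024,
        height=1024,
        n_lesions=2,
        lesion_axis_range=(36, 60),
        max_lesion_fraction=0.05,
        seed=42,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def small_pyramid(small_slide):
    """Three-level pyramid of the small slide (tile 64 so every level tiles)."""
    return TilePyramid.from_image(
        small_slide.image, PyramidConfig(tile_size=64, num_levels=3, zoom_step=2)
    )
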