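import numpy as np
import pytest

from explantkit.image_pipeline import analyze_image
from explantkit.synthetic_data import (
    BodySpec,
    DirectionSpec,
    ExplantImageSpec,
    generate_explant_image,
)


@pytest.fixture(scope="session")
def small_explant():
    """One modest synthetic explant image with well-separated neurites."""
    spec = ExplantImageSpec(
        image_shape=(1024, 1024),
        body=BodySpec(area_um2=15_000.0),
        n_start_points=10,
        neurites_per_start=(1, 2),
        branch_probability=0.0,
        length_median_um=120.0,
        heading_jitter_deg=1.5,
        direction=DirectionSpec(kind="spaced"),
        seed=7,
    )
    img, gt = generate_explant_image(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def small_explant_analysis(small_explant):
    spec, img, gt = small_explant
    mask, body, sg, metrics = analyze_image(img[1], spec.pixel_size_um)
    return spec, gt, mask, body, sg, metrics


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
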