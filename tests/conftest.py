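import numpy as np
import pytest

from hipscreen.phantom import PhantomSpec, render_frame


def clean_spec(alpha=60.0, fhc=0.5, radius=30.0, size=256, seed=0, **kw):
    """A noise-free phantom spec with coverage given as a fraction."""
    return PhantomSpec(
        image_height_px=size, image_width_px=size, alpha_true=alpha,
        head_radius_px=radius, head_offset_px=(2 * fhc - 1) * radius,
        speckle_strength=0.0, blur_sigma_px=0.0, shadow_strength=0.0,
        seed=seed, **kw)


@pytest.fixture
def clean_frame():
    """(image, truth) of a canonical noise-free standard-plane frame."""
    return render_frame(clean_spec(), 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230607)
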