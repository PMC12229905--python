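import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from follimap import (
    PRESETS,
    extract_dots,
    extract_mask,
    render_annotation_image,
    simulate_section,
)


@pytest.fixture(scope="session")
def imcg_section():
    """One standard-size IMCG-preset section (9.26 mm²)."""
    return simulate_section(PRESETS["IMCG"].to_config(9.26, seed=42))


@pytest.fixture(scope="session")
def rendered_imcg(imcg_section):
    """The same section rendered and re-extracted."""
    scale = imcg_section.config_used.mm_per_pixel
    image = render_annotation_image(imcg_section)
    return {
        "section": imcg_section,
        "image": image,
        "points": extract_dots(image, scale),
        "mask": extract_mask(image, scale),
        "scale": scale,
    }


def make_blank(h=200, w=200):
    return np.zeros((h, w, 3), dtype=np.uint8)


def draw_dot(img, r, c, color, radius=2):
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    img[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = color
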