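import numpy as np
import pytest

from brightcell.scenes import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 256x256 scene with interior cells."""
    spec = SceneSpec(
        image_size_px=(256, 256),
        n_mcf7=3,
        n_wbc=6,
        n_debris=2,
        interior_margin_px=18,
        seed=42,
    )
    return spec, generate_scene(spec)


def disk_image(shape=(128, 128), center=(60, 70), radius=12, bg=200, fg=120):
    """Uniform background with one darker disk (x, y center convention)."""
    img = np.full(shape, bg, dtype=np.uint8)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    img[(xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2] = fg
    return img


def disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
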