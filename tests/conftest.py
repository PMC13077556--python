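import numpy as np
import pytest

from cryoev.simulate import SceneSpec, default_class, simulate_micrograph


@pytest.fixture(scope="session")
def vesicle_field():
    """One deterministic 512x512 field of bilayer vesicles (no rim)."""
    spec = SceneSpec(image_shape=(512, 512),
                     particle_classes=(default_class("EV_bilayer", density=40.0),),
                     hole_rim_present=False, seed=42)
    return simulate_micrograph(spec)


@pytest.fixture(scope="session")
def blank_field():
    spec = SceneSpec(image_shape=(512, 512), particle_classes=(),
                     hole_rim_present=False, seed=7)
    return simulate_micrograph(spec)


def patches_around_particles(micrograph, truth, class_name="EV_bilayer",
                             size=96, extra_background=2, rng=None):
    """Cut training patches centred on truth particles plus a few random
    background windows; labels come from the truth class mask."""
    rng = rng or np.random.default_rng(0)
    img = micrograph.pixels
    mask = truth.class_masks[class_name]
    h, w = img.shape
    patches, labels = [], []
    for p in truth.particles:
        y0 = min(max(int(p.y) - size // 2, 0), h - size)
        x0 = min(max(int(p.x) - size // 2, 0), w - size)
        patches.append(img[y0:y0 + size, x0:x0 + size])
        labels.append(mask[y0:y0 + size, x0:x0 + size])
    for _ in range(extra_background):
        y0 = int(rng.integers(0, h - size))
        x0 = int(rng.integers(0, w - size))
        patches.append(img[y0:y0 + size, x0:x0 + size])
        labels.append(mask[y0:y0 + size, x0:x0 + size])
    return patches, labels
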