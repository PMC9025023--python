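import numpy as np
import pytest


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius * radius


@pytest.fixture
def make_disc():
    return disc_mask


@pytest.fixture
def tangent_discs_mask():
    """Two crisp digital discs of radius 30 touching at a single pixel."""
    return disc_mask((100, 170), (50, 50), 30) | disc_mask((100, 170), (50, 110), 30)


@pytest.fixture
def pair_scene():
    """Rendered backlit scene: one tangent pair plus two singles."""
    from pearlseg.synth import SceneSpec, generate_scene

    spec = SceneSpec(
        clusters=(2, 1, 1),
        grades="A1",
        axis_ratio=1.0,
        contact_angles=[[45.0], [], []],
        seed=3,
    )
    return generate_scene(spec)
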