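"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest

from specklesplice.synthgen import SceneSpec, generate_fish_scene


def small_scene_spec(**overrides):
    """A compact 25-cell scene that keeps unit tests fast."""
    defaults = dict(
        image_height_px=560,
        image_width_px=560,
        n_cells=25,
        channel_rates={"KCC2": 8.0, "NKCC1": 8.0},
        seed=7,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    spec = small_scene_spec()
    bundle, truth = generate_fish_scene(spec)
    return spec, bundle, truth


@pytest.fixture()
def disk_image():
    """Factory: binary-style intensity image with bright disks."""

    def make(shape, centers, radius, amplitude=1000.0):
        img = np.zeros(shape)
        rr = np.arange(shape[0])[:, None]
        cc = np.arange(shape[1])[None, :]
        for r, c in centers:
            img[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = amplitude
        return img

    return make
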