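import numpy as np
import pytest

from lcdmcensor import (
    DistanceSet,
    GroupedDistances,
    generate_slab_phantom,
    generate_shell_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20131014)


@pytest.fixture(scope="session")
def slab():
    """Flat-slab phantom: GM above z=0, WM below, 3 mm thick."""
    return generate_slab_phantom(thickness=3.0, lateral_extent=5.0, h=0.5,
                                 mesh_spacing=0.1)


@pytest.fixture(scope="session")
def shell():
    """Spherical-shell phantom, inner radius 2 mm, outer 4 mm."""
    return generate_shell_phantom(inner_radius=2.0, outer_radius=4.0, h=0.5,
                                  subdivisions=3)


def make_distance_set(values, subject="s1", group="A", hemisphere="left"):
    return DistanceSet(subject, group, hemisphere,
                       np.empty((0, 3), dtype=int),
                       np.asarray(values, dtype=float))


@pytest.fixture
def grouped_random(rng):
    """Three groups of pooled distances on [0, 5.5] with distinct sizes."""
    return GroupedDistances(
        "left",
        {
            "A": rng.uniform(0, 5.5, size=400),
            "B": rng.uniform(0, 5.5, size=500),
            "C": rng.uniform(0, 5.5, size=300),
        },
        {"A": 2, "B": 2, "C": 1},
    )
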