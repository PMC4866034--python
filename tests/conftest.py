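import numpy as np
import pytest

import fcseg as F

# Shape pool for tiny-volume randomized checks: every shape stays within the
# 32-voxel brute-force guard and is cheap to enumerate exhaustively.
TINY_SHAPES = [
    (1, 1, 1), (2, 1, 1), (3, 1, 1), (5, 1, 1), (2, 2, 1), (3, 2, 1),
    (4, 2, 1), (2, 2, 2), (3, 3, 1), (3, 2, 2), (4, 2, 2), (4, 4, 1),
    (3, 3, 2), (2, 2, 4), (6, 2, 1),
]


def make_tiny_case(rng: np.random.Generator, shape=None, intensity_max=30):
    """Random small volume + single random seed + LUT estimated from it."""
    if shape is None:
        shape = TINY_SHAPES[rng.integers(len(TINY_SHAPES))]
    data = rng.integers(0, intensity_max + 1, size=shape).astype(np.int32)
    vol = F.Volume3D(data, intensity_max=intensity_max)
    seed = tuple(int(rng.integers(0, s)) for s in shape)
    seeds = F.SeedSet((seed,))
    model = F.estimate_model(vol, seeds, radius=1)
    lut = F.build_lut(model, vol.intensity_max)
    return vol, seeds, lut


@pytest.fixture
def tiny_case_factory():
    return make_tiny_case


@pytest.fixture(scope="session")
def fig2_case():
    """fig-2-style corridor fixture with its seed-only affinity model."""
    vol, seeds, part, sched = F.make_fig2_fixture()
    model = F.estimate_model(vol, seeds, radius=0)
    lut = F.build_lut(model, vol.intensity_max)
    return vol, seeds, part, sched, lut


@pytest.fixture(scope="session")
def small_phantom_case():
    """One 16^3 noisy tube phantom with reference scene, shared read-only."""
    spec = F.PhantomSpec(
        shape=(16, 16, 16),
        centerline=((3.0, 4.0, 3.0), (8.0, 12.0, 8.0), (12.0, 6.0, 13.0)),
        radius=2.0, rng_seed=11,
    )
    vol, mask, seeds = F.generate_phantom(spec)
    model = F.estimate_model(vol, seeds, radius=2)
    lut = F.build_lut(model, vol.intensity_max)
    ref = F.kfoe_reference(vol, seeds, lut)
    return vol, seeds, lut, ref
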