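import numpy as np
import pytest

from exactnet.imgio import Box3D, LabelMap
from exactnet.phantom import NoduleSpec, PhantomSpec, generate_phantom, sample_center_in_lobe


def boxes_to_mask(boxes, shape):
    """Test-only rasterizer: paint each box's extent with its class label."""
    grid = np.zeros(shape, dtype=np.int32)
    for b in boxes:
        grid[b.slices()] = b.class_id
    return LabelMap(labels=grid)


@pytest.fixture(scope="session")
def lul_phantom():
    """48^3 phantom with two solid nodules in the left upper lobe."""
    rng = np.random.default_rng(7)
    base = generate_phantom(PhantomSpec(grid_shape=(48, 48, 48), seed=7))
    c1 = sample_center_in_lobe(base.lobes, "LUL", 4.5, rng)
    c2 = sample_center_in_lobe(base.lobes, "LUL", 3.5, rng, avoid=[(c1, 4.5)])
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        seed=7,
        nodules=(
            NoduleSpec("LUL", c1, 4.5),
            NoduleSpec("LUL", c2, 3.5),
        ),
    )
    return generate_phantom(spec)


def random_boxes(rng, n, grid=20, max_side=6):
    out = []
    for _ in range(n):
        lo = rng.integers(0, grid - max_side, size=3)
        side = rng.integers(1, max_side + 1, size=3)
        out.append(
            Box3D(
                lo=tuple(int(v) for v in lo),
                hi=tuple(int(v) for v in lo + side),
                score=float(rng.random()),
            )
        )
    return out
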