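import numpy as np
import pytest
from hypothesis import settings

from angioct import CTSimParams, TreeParams, make_phantom
from angioct.volume import ScalarVolume

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_phantom():
    """One modest phantom with ground truth, shared across tests."""
    tp = TreeParams(domain_shape=(120, 120, 120), rng_seed=7)
    sp = CTSimParams(rng_seed=77)
    tree, mask, vol = make_phantom(tp, sp)
    return tp, tree, mask, vol


def make_cylinder(shape, radius_vox, axis=0, center=None):
    """Axis-aligned solid cylinder mask (closed-ball rule, grid-centered)."""
    shape = tuple(shape)
    trans = [a for a in range(3) if a != axis]
    if center is None:
        center = [(shape[a] - 1) // 2 for a in trans]
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[a] - center[i]) ** 2 for i, a in enumerate(trans))
    return d2 <= radius_vox ** 2


def cylinder_volume(shape, radius_um, voxel_size, axis=0, intensity=(100.0, 500.0)):
    bg, fg = intensity
    mask = make_cylinder(shape, radius_um / voxel_size, axis=axis)
    data = np.where(mask, fg, bg).astype(np.float32)
    return mask, ScalarVolume(data, voxel_size)
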