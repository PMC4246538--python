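"""Generate one digital vascular-tree phantom and its simulated CT scan.

Builds a random tree of curved cylindrical vessel segments (area is
conserved at every bifurcation, minimum diameter two voxels), voxelizes
it to a ground-truth mask and degrades it with Gaussian blur and noise.
"""

import numpy as np

from angioct import CTSimParams, TreeParams, make_phantom
from angioct.phantom import check_area_conservation

params = TreeParams(domain_shape=(160, 160, 160), voxel_size=12.0, rng_seed=1)
tree, true_mask, volume = make_phantom(params, CTSimParams(rng_seed=1))

_, diameters = tree.centerline_samples()
print(f"segments:            {len(tree.segments)}")
print(f"diameter range:      {diameters.min():.0f}-{diameters.max():.0f} um")
print(f"area conservation:   {check_area_conservation(tree)}")
print(f"true vessel voxels:  {true_mask.sum()} "
      f"({100 * true_mask.mean():.2f}% of the domain)")
print(f"simulated intensity: {volume.data.min():.0f}..{volume.data.max():.0f} "
      "(background 100, vessels 500, blurred + noisy)")
# The diameter range shows the area-conserving bifurcations at work:
# every split shrinks the children, never below the two-voxel minimum.
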