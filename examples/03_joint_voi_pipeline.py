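"""Anatomical VOIs and the full hybrid pipeline on a joint phantom.

Two bone-like bodies around a joint gap are virtually removed, the knee
joint cavity VOI_KJC = VOI_TFC \\ VOI_TF is extracted, a capsule sphere
(2.5 x the cavity bounding sphere) is split into four concentric shells,
and the MSLAT hybrid segmentation plus per-VOI morphometry is run.
"""

from pathlib import Path

from angioct import CTSimParams, TreeParams, make_phantom
from angioct.config import PipelineConfig
from angioct.phantom import BonePhantomParams, generate_bone_phantom
from angioct.pipeline import run_pipeline

shape = (96, 96, 96)
tree_params = TreeParams(domain_shape=shape, voxel_size=15.0, min_radius=15.0,
                         root_radius=60.0, rng_seed=30)
_, vessels, _ = make_phantom(tree_params, CTSimParams(rng_seed=30))
bone_params = BonePhantomParams(gap_voxels=16, body_radius_fraction=0.28,
                                sim=CTSimParams(rng_seed=31, noise_sigma=20.0))
tibia, femur, volume = generate_bone_phantom(shape, 15.0, bone_params,
                                             vessel_mask=vessels)

config = PipelineConfig(out_dir="scratch/example_joint_run")
config.voi.tibia_seeds = [[10, 48, 48]]
config.voi.femur_seeds = [[85, 48, 48]]
config.voi.closing_radius = 12
config.segmentation.method = "mslat"

out = run_pipeline(config, volume=volume)
print(f"results in {out}")
print(Path(out, "morphometry.csv").read_text())
# One row per concentric shell VOI_1..VOI_4 plus the whole capsule:
# TV/VV in mm3, VV/TV in %, surface in mm2, direct (V.Th3D, um) and
# rod-model (V.Th2D/V.Sp2D/V.N2D) parameters and the component count.
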