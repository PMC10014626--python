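"""Two-stage rigid registration: masks first, then densities.

A phantom is displaced by a known rigid motion (7 deg rotation, a few mm of
translation); the mask stage recovers a robust initial alignment and the
density stage refines it by mutual information.  The printed errors compare
the recovered transform with the ground truth.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from femfall import DensityVolume, PhantomSpec, apply_rigid, generate_phantom, rigid_register
from femfall.geometry import RigidTransform

case = generate_phantom(PhantomSpec(noise_sd=0.0, seed=2))
bmd = case.truth_bmd
mask = DensityVolume((case.mask.values > 0).astype(np.uint8),
                     bmd.spacing, bmd.origin, "label")

R = Rotation.from_euler("z", 7, degrees=True).as_matrix()
center = bmd.origin + bmd.world_extent() / 2
T_true = RigidTransform(R, center - R @ center + np.array([4.0, -3.0, 2.0]))
moved_mask = apply_rigid(mask, T_true.inverse(), mask, order=0)
moved_bmd = apply_rigid(bmd, T_true.inverse(), bmd, order=3)

stage1 = rigid_register(mask, moved_mask, stage="masks")
stage2 = rigid_register(bmd, moved_bmd, stage="densities", init=stage1.transform)

pts = mask.index_to_world(np.argwhere(mask.values > 0)[::31])
for name, res in (("masks", stage1), ("densities", stage2)):
    T = res.transform
    dR = T.rotation @ T_true.rotation.T
    ang = np.degrees(np.arccos(np.clip((np.trace(dR) - 1) / 2, -1, 1)))
    disp = np.linalg.norm(T.apply(pts) - T_true.apply(pts), axis=1).max()
    print(f"{name:<10s} rotation error {ang:.3f} deg, "
          f"max point error {disp:.3f} mm, "
          f"MI {res.metric_initial:.3f} -> {res.metric_final:.3f}")
# Sub-voxel, sub-tenth-degree recovery after the density refinement; the MI
# metric (more negative = better) improves at each stage.
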