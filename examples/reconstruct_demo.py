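"""Iterative reconstruction at a glance: the effect of the relative
difference prior.

Simulates a noisy SPECT acquisition of a coarse phantom and reconstructs
it with BSREM at increasing regularization strength beta (beta = 0 is
plain OSEM); the RDP penalty value summarises volume roughness.
"""

import numpy as np

from replanar import (GridGeometry, PhantomSpec, ReconConfig,
                      bsrem_rdp_reconstruct, default_spect_angles,
                      make_phantom, rdp_penalty, simulate_spect)

grid = GridGeometry((16, 16, 16), voxel_size_mm=19.68)
activity, mu, _ = make_phantom(PhantomSpec(grid=grid, myo_to_rib_ratio=1.5), seed=3)

proj = simulate_spect(activity, mu, angles_deg=default_spect_angles(24),
                      seed=10, noiseless=False)

for beta in (0.0, 0.4, 5.0):
    vol = bsrem_rdp_reconstruct(proj, mu, ReconConfig(
        algorithm="bsrem_rdp", beta=beta, gamma=4.0,
        n_iterations=30, n_subsets=4))
    nrmse = np.linalg.norm(vol.data - activity.data) / np.linalg.norm(activity.data)
    print(f"beta = {beta:3.1f}: NRMSE vs truth {nrmse:.3f}, "
          f"RDP roughness penalty {rdp_penalty(vol.data, 4.0):.1f}")

print("\nRaising beta monotonically lowers the roughness penalty of the "
      "converged volume; the study value 0.4 is a light touch at these "
      "count levels.")
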