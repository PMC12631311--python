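"""β-sheet content of a folded hairpin vs an extended chain.

The βRMSD collective variable scores 3-residue backbone segment pairs
against ideal β-sheet templates through a rational switching function.
A noiseless folded hairpin gives its designed strand pair a score of
exactly 1; a straight extended chain scores ~0.
"""

import numpy as np

from mutadyn.core import TrajectorySeries
from mutadyn.cv import BetaRmsdConfig, beta_rmsd, beta_rmsd_pairs, switching_function
from mutadyn.peptides import build_backbone
from mutadyn.synthetic import TwoStateSpec, gen_two_state_trajectory

folded, _ = gen_two_state_trajectory(
    TwoStateSpec(n_frames=3, seed=0, noise_sigma=0.0, p_folded=0.999999,
                 distance_sd=0.0))
pairs, scores = beta_rmsd_pairs(folded, BetaRmsdConfig(mode="antiparallel"))
k = pairs.index((0, 8))   # segments 1532-1534 and 1540-1542
print(f"hairpin: designed pair score = {scores[0, k]:.6f} (S(0) = 1)")
print(f"hairpin: total antiparallel βRMSD = {scores[0].sum():.3f} over {len(pairs)} pairs")

ext = build_backbone(["ALA"] * 11, 180.0, 180.0, first_res_id=1532)
ext_traj = TrajectorySeries(ext, ext.coords[None], np.array([0.0]))
print(f"extended chain: total βRMSD = {beta_rmsd(ext_traj).values[0]:.4f}")

print(f"switching function at r = r0: {switching_function(0.1, 0.1, 8, 12):.4f} "
      f"(limit n/m = {8 / 12:.4f})")
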