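"""Winner-take-all parcellation of synthetic voxel connectivity profiles.

Each caudate voxel carries a connection-probability vector over five cortical
targets; voxels are assigned to their maximal-probability target.  With
sharply peaked profiles the planted subdivisions are recovered almost
perfectly (Dice near 1); with flat profiles recovery drops to chance (1/5).
"""

import numpy as np

from cbtc import winner_take_all
from cbtc.parcellation import recovery_dice
from cbtc.simulate import simulate_voxel_profiles

targets = ("MPFC", "DLPFC", "M1", "PMC", "OFC")
for kappa in (1000.0, 5.0, 1.0):
    prof = simulate_voxel_profiles("CAU", targets, voxels_per_subdivision=60,
                                   kappa=kappa, seed=3)
    pm = winner_take_all(prof.probs, prof.targets, "CAU", tau=0.01)
    d = recovery_dice(pm, prof.true_labels)
    print(f"concentration kappa={kappa:>6}: mean Dice vs planted labels = "
          f"{np.mean(list(d.values())):.3f}  "
          f"(e.g. CAU_M1 subdivision: {d['M1']:.3f})")
print("\nDice 1.0 = the connectivity-defined subdivision exactly matches the "
      "planted territory; 0.2 = chance with five targets")
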