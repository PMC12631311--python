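"""Interaction fingerprint of a probe residue with the 30% occupancy filter.

A scripted 100-frame trajectory keeps a hydrogen bond in 99 frames; the
fingerprint reports the occupancy of each (type, partner) contact and the
filter keeps only contacts with probability strictly above 30%.
"""

import numpy as np

from mutadyn.core import TrajectorySeries
from mutadyn.interactions import filter_interactions, interaction_probability
from mutadyn.synthetic import gen_interaction_fixture

near = gen_interaction_fixture("hydrogen_bond", distance=2.9, angle=160.0)
far = gen_interaction_fixture("hydrogen_bond", distance=6.0)

frames = [near] * 99 + [far]
traj = TrajectorySeries(near, np.stack([f.coords for f in frames]),
                        np.arange(100, dtype=float))

records = interaction_probability(traj, probe=1)
kept = filter_interactions(records, threshold=0.30)

print("Type            Residue  Probability (%)")
for r in kept:
    print(f"{r.type.replace('_', ' ').capitalize():15s} {r.partner:7d}"
          f"  {round(100 * r.probability):15d}")
print(f"({len(records)} raw contacts, {len(kept)} above the strict 30% filter)")
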