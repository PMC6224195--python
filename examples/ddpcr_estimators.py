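"""Compare the raw droplet-count ratio with the Poisson-corrected estimator.

At low template occupancy (~0.1 per droplet) nearly every positive droplet
holds one template and the raw count ratio tracks the allele proportion.
At occupancy 2.0 most droplets are positive in the abundant channel, the
ratio saturates toward 0.5, and only the occupancy correction
lambda = -ln(1 - fraction positive) recovers the truth.
"""

import numpy as np

from compfit import (
    poisson_corrected_proportion,
    proportion_from_counts,
    simulate_droplet_readout,
)

rng = np.random.default_rng(7)
true_p = 0.8

for occupancy in (0.1, 2.0):
    raw, corrected = [], []
    for _ in range(500):
        counts = simulate_droplet_readout(true_p, occupancy, 15000, rng=rng)
        raw.append(proportion_from_counts(counts))
        corrected.append(poisson_corrected_proportion(counts))
    print(f"occupancy {occupancy:3.1f}: raw ratio mean = {np.mean(raw):.3f}, "
          f"Poisson-corrected mean = {np.mean(corrected):.3f} "
          f"(true {true_p})")

print("\nThe raw ratio is the trajectory estimator used by the pipeline and")
print("is accurate in its low-occupancy operating range; the corrected")
print("estimator stays accurate even when droplets saturate.")
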