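"""Behavioral fractions and group comparisons.

Computes bordering fractions (animals within 1 mm of the lawn edge) for
three strains and compares them by one-way ANOVA with Tukey's HSD, the
test used for multi-strain behavioral panels.
"""

import numpy as np

from compfit import BehaviorCounts, bordering_fraction, compare_groups, exploration_fraction

rng = np.random.default_rng(3)
panels = {
    "N2": 0.10,              # solitary: low bordering
    "N2_glb-5,npr-1": 0.75,  # ancestral alleles: social, high bordering
    "CB4856": 0.80,
}
groups = {}
for strain, rate in panels.items():
    fracs = []
    for _ in range(8):  # 8 assay plates of 150 animals
        counts = BehaviorCounts(strain, "21% O2", n_scored=150,
                                n_positive=int(rng.binomial(150, rate)))
        fracs.append(bordering_fraction(counts))
    groups[strain] = fracs
    print(f"{strain}: mean bordering fraction = {np.mean(fracs):.3f}")

print(f"\nexploration fraction for 52 of 105 grid squares = "
      f"{exploration_fraction(52):.3f}")

print("\nANOVA + Tukey HSD:")
print(compare_groups(groups, test="anova_tukey").to_string(index=False))
print("\nAdjusted p < 0.05 marks strain pairs whose bordering differs beyond")
print("plate-to-plate noise.")
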