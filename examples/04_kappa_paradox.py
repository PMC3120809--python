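"""Reproduce the kappa paradox by simulation.

Kappa corrects observed agreement for the agreement expected by chance.
When one rater puts ~90% of ratings in a single category, chance
agreement is already huge, so kappa hovers near zero no matter how close
the raters are.  This script draws 50 replicates of a ceiling-effect
trial arm and tabulates how often kappa stays below 0.10 while more than
90% of paired differences are within one scale point.
"""

import numpy as np

from ordagree import (
    build_contingency,
    cohen_kappa,
    difference_distribution,
    percent_within_k,
)
from ordagree.simulate import ceiling_preset, generate

cfg = ceiling_preset()
rng = np.random.default_rng(7)

paradox = 0
R = 50
kappas, within = [], []
for _ in range(R):
    pairs = generate(cfg, rng.integers(2**31))
    table = build_contingency(pairs)
    k = cohen_kappa(table, "unweighted").estimate
    w1 = percent_within_k(difference_distribution(table), 1)
    kappas.append(k)
    within.append(w1)
    if k < 0.10 and w1 > 90.0:
        paradox += 1

print(f"{R} replicates of 44 clusters x 12 encounters, 5-point scale,")
print(f"~90% patient ceiling, physician latent bias +0.35:")
print(f"  median kappa (unweighted)      : {np.median(kappas):.3f}")
print(f"  median % within +/-1 point     : {np.median(within):.1f}")
print(f"  paradox (kappa<0.10, >90% near): {paradox}/{R} replicates")
print()
print("Near-perfect practical agreement, near-zero chance-corrected")
print("agreement — the reason skewed satisfaction data needs the")
print("Bland-Altman view instead of a single coefficient.")
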