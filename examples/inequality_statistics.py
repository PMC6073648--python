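"""Wealth-distribution reductions on a toy population of ten men.

Shows the empirical Gini, the Lorenz curve area identity, the minimal
fraction of men holding half the wealth, and the 2-polygyny wealth
threshold (midpoint between the mean wealth of 1-wife and 2-wife men).
"""

import numpy as np

from polythresh import (
    gini,
    lorenz,
    polygyny_wealth_threshold,
    proportion_rich_share,
    two_class_summary,
)

wealth = np.array([1, 1, 2, 2, 3, 3, 4, 6, 8, 20], dtype=float)
wives = np.array([0, 1, 1, 1, 1, 1, 2, 1, 2, 3])

g = gini(wealth)
curve = lorenz(wealth)
print(f"Gini coefficient: {g:.3f} (2 x area between Lorenz curve and diagonal: "
      f"{curve.gini_area():.3f})")
print(f"bottom 50% of men hold {curve.wealth_share_below(0.5):.1%} of the wealth")

theta_hat = proportion_rich_share(wealth, 0.5)
summary = two_class_summary(wealth, 0.5)
print(f"minimal fraction of men holding >= 50% of wealth: {theta_hat:.2f} "
      f"(their mean wealth is {summary.wealth_ratio:.1f}x the rest)")

psi = polygyny_wealth_threshold(wealth, wives)
print(f"2-polygyny threshold psi = {psi.psi:.2f}; "
      f"{psi.proportion_above:.0%} of men sit above it")
print("\nA small rich class can hold most wealth (high Gini) while few men\n"
      "clear the wealth level at which second wives become typical.")
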