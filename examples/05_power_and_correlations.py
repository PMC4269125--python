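"""A-priori power and correlation machinery.

Computes the Monte-Carlo power of a correlational design (two-sided Pearson
test), the Fisher-z confidence interval for a cohort-sized correlation, and a
partial correlation controlling for a mediator.
"""

import numpy as np

from twostep import partial_correlation, pearson_ci, power_simulation

power29 = power_simulation(0.45, 29, n_reps=100_000, seed=1)
power27 = power_simulation(0.45, 27, n_reps=100_000, seed=1)
print(f"power to detect r = 0.45 at alpha = .05: n=29 -> {power29:.1%}, "
      f"n=27 -> {power27:.1%}")

rng = np.random.default_rng(2)
n = 27
speed = rng.standard_normal(n)
weight = 0.6 * speed + 0.8 * rng.standard_normal(n)
rewards = 0.7 * weight + 0.7 * rng.standard_normal(n)

r, lo, hi, p = pearson_ci(speed, rewards)
print(f"speed-rewards correlation: r = {r:.2f} [{lo:.2f}, {hi:.2f}], p = {p:.3f}")

rp, lo_p, hi_p, pp = partial_correlation(speed, rewards, weight)
print(f"controlling the weight:    r = {rp:.2f} [{lo_p:.2f}, {hi_p:.2f}], p = {pp:.3f}")
print("\nattenuation of the partial correlation indicates the weight mediates "
      "the speed-reward link.")
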