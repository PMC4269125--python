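"""Simulate the two-step task environment.

Generates the four drifting reward probabilities, draws transitions for a
block of first-stage choices, and shows the payout rule.
"""

import numpy as np

from twostep import TaskConfig, compute_payout, generate_walks, step_transition

config = TaskConfig()
walks = generate_walks(config, seed=1)
print(f"walk range: [{walks.probs.min():.3f}, {walks.probs.max():.3f}] "
      f"(reflecting bounds are [{config.walk_lo}, {config.walk_hi}])")

rng = np.random.default_rng(2)
n = 5000
common = np.mean([step_transition(0, config, rng).was_common for _ in range(n)])
print(f"common-transition rate over {n} draws: {common:.3f} "
      f"(designed rate {config.p_common})")

total = 0.20 * 120  # e.g. 120 wins of 20 cents
print(f"payout for {total:.2f} EUR in wins: {compute_payout(total, config):.2f} EUR "
      "(one third, clamped to [3, 10])")
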