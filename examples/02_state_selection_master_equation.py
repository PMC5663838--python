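"""State selection by extensive entropy production (exact master equation).

Solves the exact stationary pmf at Ω = 100 across the bistable window,
splits it at the separatrix, and shows that the state with the larger
probability weight is the one with the larger extensive entropy
production rate dS_{i,k}/dt — the entropy-production state-selection
principle.  Also locates the critical driving b_c where dominance flips.
"""

import numpy as np

from schloegl import (
    SchloeglParams,
    critical_b,
    partition_states,
    stationary_distribution,
)

params = SchloeglParams(omega=100.0)

print(f"{'b':>5} {'w_low':>8} {'w_high':>8} {'EP_low':>10} {'EP_high':>10}"
      f" {'heavier':>8} {'more EP':>8}")
for b in np.arange(3.4, 4.01, 0.1):
    p = params.with_(b_conc=b)
    part = partition_states(stationary_distribution(p), p)
    heavier = "high" if part.weights[1] > part.weights[0] else "low"
    more_ep = "high" if part.ep_rates[1] > part.ep_rates[0] else "low"
    print(f"{b:5.2f} {part.weights[0]:8.4f} {part.weights[1]:8.4f} "
          f"{part.ep_rates[0]:10.3f} {part.ep_rates[1]:10.3f} "
          f"{heavier:>8} {more_ep:>8}")

crit = critical_b(params)
print(f"\nweight crossing   b_c = {crit['b_weight']:.4f}")
print(f"EP-rate crossing  b   = {crit['b_ep']:.4f}")
print("\nOutside a narrow band around b_c the two orderings agree: the"
      " heavier state is the bigger (extensive) entropy producer, even"
      " though per volume the high state always dissipates more.")
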