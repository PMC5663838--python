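"""Flux-constrained Langevin dynamics, path action and trajectory entropy.

Simulates the three-variable system (x, a, b) with the conversion flux F
pinned to a target steady state, decomposes the Onsager-Machlup action
of a path into its kinetic-potential, entropy-production and curvature
parts, and shows that the driven high state produces entropy along
trajectories while the equilibrium point does not.
"""

import math

import numpy as np

from schloegl import (
    SchloeglParams,
    langevin_entropy_production,
    path_action,
    simulate_langevin,
    steady_state_setup,
    weight_terms,
)

params = SchloeglParams()  # b = 4, Ω = 100
setup = steady_state_setup(params, "high")
print(f"high state: x* = {setup['x_star']:.4f}, pinned flux F = "
      f"{setup['F']:.4f}, g_a* = {setup['g_a']:.3f}, g_b* = {setup['g_b']:.3f}")

path = simulate_langevin(params, "high", dt=1e-3, t_max=40.0, seed=1,
                         n_paths=20)
ab = path_action(path, params, path_index=0)
print("\naction decomposition of one 40-time-unit path:")
print(f"  kinetic-potential : {ab.kinetic_potential:12.1f}")
print(f"  entropy production: {ab.entropy_production:12.1f}")
print(f"  noise/curvature   : {ab.noise:12.1f}")
print(f"  total             : {ab.total:12.1f}")

dS = langevin_entropy_production(params, "high", dt=1e-3, t_max=120.0,
                                 burn_in=40.0, seed=2, n_paths=100)
se = dS.std(ddof=1) / math.sqrt(len(dS))
print(f"\ndriven high state: <ΔS_Γ> = {dS.mean():.1f} ± {se:.1f} k_B "
      f"over t = 80 (positive: entropy is produced)")

p_eq = SchloeglParams(b_conc=1 / 6, omega=10_000.0)
dS0 = langevin_entropy_production(p_eq, "low", dt=1e-3, t_max=120.0,
                                  burn_in=40.0, seed=3, n_paths=100)
se0 = dS0.std(ddof=1) / math.sqrt(len(dS0))
print(f"equilibrium (F = 0, b0): <ΔS_Γ> = {dS0.mean():.3f} ± {se0:.3f} k_B "
      f"(consistent with zero)")

clamped = {
    st: simulate_langevin(params, st, eps=1e-3, dt=1e-3, t_max=40.0,
                          seed=10 + i, n_paths=40, clamp_reservoirs=True)
    for i, st in enumerate(("low", "high"))
}
wt = weight_terms(clamped, params, burn_in=10.0)
print("\nper-state weight terms (reservoir-clamped ensembles, ε = 1e-3):")
for st in ("low", "high"):
    print(f"  {st:5s}: classical action rate = "
          f"{wt[st]['classical_action_rate']:8.3f}, "
          f"entropy-production term = {wt[st]['schnakenberg_rate']:8.3f}")
print(f"state maximizing the EP term: {wt['low']['max_ep_state']}")
print("\nIn the steady-state weight, the EP term enters with a favorable"
      " sign: the high state is preferred by dissipation.")
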