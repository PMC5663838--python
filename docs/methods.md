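# Methods

## Model and conventions

The Schlögl network A ⇌ X, 3X ⇌ 2X + B is treated with reservoir
concentrations a and b held fixed.  Defaults: k₊₁a = 0.5, k₋₁ = 3,
k₊₂ = k₋₂ = 1.  Time is measured in units of 1/k₊₂ (the model never
fixes an absolute time scale); entropy is in units of k_B; Ω is the
dimensionless reaction volume, so molecule numbers are X = Ωx.
Detailed balance holds at b₀ = k₊₂k₊₁a/(k₋₁k₋₂) = 1/6.

Microscopic propensities out of state X:

    W₊₁ = k₊₁ a Ω              (X → X+1)
    W₋₁ = k₋₁ X                (X → X−1)
    W₊₂ = k₊₂ X(X−1)(X−2)/Ω²   (X → X−1)
    W₋₂ = k₋₂ b X(X−1)/Ω       (X → X+1)

These are the unique mass-action forms that (i) converge to the
macroscopic rate laws w±ᵣ under X = Ωx, Ω → ∞, and (ii) satisfy exact
channel-wise detailed balance at b₀, where the stationary pmf is
Poisson(Ω/6).  Both properties are verified by tests.

## Stationary and transient master equation

The chain is nearest-neighbour and reflecting at 0, so the stationary
pmf obeys the zero-net-flux bond recursion
[W₊₁+W₋₂](X)P(X) = [W₋₁+W₊₂](X+1)P(X+1), accumulated in log space and
normalized.  Automatic truncation starts at x_max = 8·Ω·x_high (the
high-state mode ≈ 3.1Ω must be deeply interior) and doubles until a
geometric tail bound, built from the terminal birth/death ratio, drops
below 1e−10.

Transient solutions propagate dP/dt = QP with the Krylov matrix
exponential (`scipy.sparse.linalg.expm_multiply`), which is exact to
machine precision for this linear stiff system; a BDF integrator with
rtol 1e−9 is kept as a cross-check.  We chose the exponential over an
implicit stepper because the entropy-balance identity
dS/dt = dS_i/dt + dS_e/dt is verified against *finite-difference*
derivatives of S(t) at spacing 1e−4, which demands propagation errors
well below 1e−9.  The cubic death rates of never-populated states
dominate the generator norm, so transient solves are run on a support
trimmed to the physically occupied range (e.g. X ≤ 90 at Ω = 10, where
the stationary mass beyond is < 1e−15).

Entropy bookkeeping sums each bond and channel once (absorbing the ½
that compensates double counting of forward/backward event pairs):
production J·ln[(W_fwd P)/(W_bwd P′)] ≥ 0 per term, flow
−J·ln(W_fwd/W_bwd).  Internal molecular entropies S⁰(X) are set to
zero throughout — the analysis never assigns them values — so the
"passive" advective entropy flow vanishes identically and the Gibbs
entropy is the distribution term −ΣP lnP alone.

## Separatrix partition and per-state entropy production

The separatrix is the interior minimum of the pmf between the two
dominant modes, detected on the log pmf after a 3-point moving maximum
(raw pmfs at Ω = 10 show single-bin noise).  Weights, means, and
extensive per-state EP rates accumulate on each side; the separatrix
bin itself splits 50/50, keeping the decomposition exactly additive
(the ambiguity is O(1/Ω)).  Per-state EP assigns each reaction event to
its source state: ep(X) = Σ_events W(X)P(X)·ln(W/W_rev); summed over X
this equals the stationary production rate exactly.

The critical driving b_c is the bisection root of
w_low(b) − w_high(b); at Ω = 100 the package finds b_c ≈ 3.60 with the
per-state EP crossing at ≈ 3.53 — close but distinct, as the weights
also feel the peak curvatures.  The reported separatrix x_min ≈ 0.94
refers to b = 3.65; the minimum moves quickly with b (≈ 0.97 at the
computed b_c), which is why the state-selection report evaluates it at
the fixed reference driving.

## WKB potential

For large Ω, p(x) ∝ N(x)exp(−ΩΦ(x)).  We use the standard 1D
birth–death eikonal Φ′(x) = ln[(w₋₁+w₊₂)/(w₊₁+w₋₂)], i.e. the log of
total death over total birth rate per volume.  A transcribed variant
that takes the log of (net rate)/(total rate) is 0 at fixed points and
negative on half the domain, so its logarithm cannot serve as Φ′; the
form used here (i) vanishes exactly at the ODE fixed points, (ii) is
the continuum limit of the exact stationary recursion, and (iii)
reduces to the detailed-balance potential at b₀ — each property is a
test.  Φ is integrated by per-segment adaptive quadrature (abs.
tolerance 1e−10) anchored at the smallest stable fixed point; Φ″ is
analytic, never finite-difference.

Two prefactor modes: `birth-death-standard`,
N(x) ∝ [(w₊₁+w₋₂)(w₋₁+w₊₂)]^(−1/2), and `constant` (peak-height
approximation).  The escape-rate ratio

    r₁→₂/r₂→₁ = √(Φ″(x₁)/Φ″(x₂)) · [N(x₂)/N(x₁)] · exp(+Ω[Φ(x₁)−Φ(x₂)])

carries its exponent with the orientation that makes the deeper well
the harder one to escape, validated against exact mean first-passage
times rather than trusted from any printed convention; the N ratio is
required by stationary flux balance w₁r₁→₂ = w₂r₂→₁ and improves the
estimate from a factor ≈ 35 to ≈ 1.5 at Ω = 30 near the crossing
(dropped in `constant` mode).  Mean first-passage times themselves use
the standard nested-sum formula evaluated with running log-sum-exp, so
extremely skewed stationary measures (e.g. pure-birth chains) stay
finite.

## Gillespie simulation

Exact SSA with numba-compiled inner loops; one RNG stream per
trajectory derived from (seed, replicate), so ensembles are
reproducible and order-independent.  Every jump contributes
ln(W_fwd/W_rev) to the cumulative medium entropy; the boundary term
ln(P(X₀)/P(X_t)) is excluded by default (negligible for long runs) and
included where the integral fluctuation theorem requires it.  Long
occupancy runs accumulate time-weighted histograms on the fly instead
of storing ~10⁸ jumps.  Burn-in defaults are stated per analysis; the
occupancy/EP cross-checks at Ω = 10, b = 4 use t = 1e5 with burn-in
100, giving total-variation agreement with the exact pmf below 0.02
(the threshold follows from the switching rate: ≈ 5·10³ basin switches
give weight errors ≈ 1.4%).

The integral-fluctuation-theorem check ⟨e^(−ΔS_total)⟩ = 1 runs on
windows of t = 0.01 at Ω = 10, b = 4 (⟨ΔS⟩ ≈ 1.3).  The estimator's
second moment is e^(2⟨ΔS⟩) for near-Gaussian ΔS, so n = 10⁴ samples
need ⟨ΔS⟩ ≲ ½ln(0.1n) ≈ 3.5; longer windows (the stationary EP rate is
≈ 129 k_B/time) are fundamentally under-sampled at any feasible n.
The CI is a 99.7% percentile bootstrap, matching the 3-SE convention
of the other stochastic checks.

## Flux-constrained Langevin system

The three concentrations q = (x, a, b) evolve with the conversion flux
F pinned to the target state's value w₊₁(x*) − w₋₁(x*), additive noise
frozen at that state, and the X-noise anticorrelated with the
reservoir noises, η_x = −(η_a + η_b), so x + a + b is conserved
exactly.  The effective temperatures g_a* = w₊₁+w₋₁, g_b* = w₊₂+w₋₂
(g_x* = g_a*+g_b*) are noise *variance* scales: η_q = √(ε g_q*)·ξ_q
with ε = 1/Ω, the chemical-Langevin magnitude.  This convention is
forced by consistency: it is the diffusion matrix of the underlying
jump process at the fixed point, it makes Var(η_x) = ε g_x* hold
exactly for the anticorrelated sum, and it keeps relative fluctuations
O(Ω^(−1/2)) so the additive-noise approximation is controlled at the
volumes studied.  The matching Onsager–Machlup action divides by g_q*
(first power — the noise variance), and total = kinetic-potential +
entropy-production + curvature parts holds exactly for the discretized
functional; the EP part includes the −Fσ_q q̇ cross-term (whose time
average vanishes at stationarity) so the identity is exact, with the
bare ∫q̇Φ′/g* form reported alongside.

All path functionals use midpoint (Stratonovich) discretization: the
noise–gradient correlation must take its Stratonovich value for the
time-reversal antisymmetry ΔS_Γ = A(−Γ) − A(Γ) to hold, which is
asserted as an exact identity on simulated paths.  Trajectory EP:

    ΔS_Γ = −2Ωt [ avg(ȧΦ′_ODE(a))/g_a* + avg(ḃΦ′_ODE(b))/g_b* ].

Long equilibrium runs use a streaming kernel (O(n_paths) memory).

Three properties of this approximation matter for interpretation:

1. **The flux-pinned low state is linearly unstable.**  On the
   conserved manifold the Jacobian at the low fixed point has a
   positive eigenvalue (≈ +0.2…+0.4 across the bistable window): the
   reservoir feedback destabilizes the low state, so the dynamic
   three-variable system literally selects the high state.  Per-state
   ensembles for *both* states therefore use `clamp_reservoirs` (a, b
   held at reservoir values; x keeps its anticorrelated noise), the
   regime in which per-basin averages exist; ensembles that switch
   basins are excluded path-wise (rare-switching conditioning) and a
   majority-escaped ensemble is an error.

2. **Equilibrium is reversible only to leading order in ε.**  The
   frozen-temperature additive-noise model at (F = 0, b₀) has a
   genuine O(ε) positive residual in ⟨ΔS_Γ⟩ (≈ 8.9 ± 0.5 k_B per 600
   time units at ε = 0.01, scaling ≈ 1/Ω; the same estimator returns
   zero on the linearized system, which is provably reversible, so
   this is not integrator bias).  Equilibrium checks run at ε = 1e−4,
   where the relative fluctuation of x₀ = 1/6 (≈ 2.4%) matches that of
   the driven high-state checks at ε = 0.01 (≈ 7.7%) — the equilibrium
   state sits close to the zero-concentration boundary and needs the
   smaller noise for the additive model to represent the (reversible)
   chemistry.  Runs with > 0.1% zero-reflected steps warn.

3. **⟨ΔS_Γ⟩ is not asserted equal to Ω·t·(Schnakenberg rate).**  The
   chain of approximations linking the path functional to the
   ensemble formula is heuristic; only the sign, the linear growth in
   t, and the state ordering of the EP terms are quantitative claims.
   The per-state Schnakenberg term matches the macroscopic rate within
   5% at ε = 1e−3; at ε = 0.01 the low state's 32% relative
   fluctuations inflate the nonlinear average by ≈ 30%, so only the
   ordering is asserted there.

## Reports

`maxepp_report` verdicts: weight/EP ordering concordance outside a
≤ 0.15-wide band around the crossing; |b_c − 3.65| ≤ 0.1; separatrix
at b = 3.65 within [0.85, 0.95]; heavier state = bigger producer at
b ∈ {3.4, 3.9}.  `minepp_report` fits log(ds_i/dt) against log(b − b₀)
for b − b₀ ∈ [1e−4, 1e−2]·b₀ and asserts slope 2 ± 0.05; at b = 2b₀
the quadratic law is off by far more than 5%, marking the regime
boundary.  All report verdicts carry a config hash and package version.

## Problem sizes

The default study conditions: Ω = 100 for all master-equation and
Langevin state-selection results (chains of ≈ 2500 states), Ω = 10 for
Gillespie cross-checks (t = 1e5, ≈ 4·10⁸ events, numba), n = 100–200
trajectories for ensemble statistics, 10⁴ samples for the fluctuation
theorem.  All stochastic assertions use 3-SE (or 99.7% bootstrap)
bands.

## Known limitations

- Single-species, well-mixed only: no spatial variant, no diffusion,
  no multi-species generalization (the CME machinery is written for
  generic 1D birth–death chains, nothing wider).
- The WKB prefactor is the standard birth–death form, not a derived
  closed form; it is validated only through density and escape-rate
  agreement.
- The Langevin model freezes noise amplitudes per target state; it is
  a small-noise approximation and its equilibrium irreversibility
  residual (point 2 above) is a property of the approximation, not of
  the chemistry.
- Tau-leaping, rare-event path sampling, and multiplicative-noise
  action functionals are out of scope.
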