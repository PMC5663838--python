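"""Flux-constrained Langevin dynamics and the Onsager-Machlup action.

The three-variable system follows the concentrations q = (x, a, b) with
the reservoirs made explicit and held stationary by an imposed
conversion flux F::

    dx/dt = w+1 - w-1 + w-2 - w+2          + η_x
    da/dt = -(w+1 - w-1)            + F    + η_a
    db/dt = -(w-2 - w+2)            - F    + η_b

Noise is additive with 'effective temperatures' frozen at the target
steady state, g_a* = w+1 + w-1 and g_b* = w+2 + w-2 (and
g_x* = g_a* + g_b*).  g* is the noise variance (diffusion) scale:
η_q = sqrt(ε·g_q*)·ξ_q, the standard chemical-Langevin magnitude, so
that Var(η_x) = ε·g_x* holds exactly for the anticorrelated X-noise
η_x = -(η_a + η_b), and the total concentration x + a + b is exactly
conserved along every path.  The small parameter is ε = 1/Ω.

The path functionals implemented are the quadratic (Onsager-Machlup)
action of the additive-noise system, its decomposition into a
kinetic-potential part, an entropy-production part and a curvature
(noise) part, and the trajectory entropy production

    ΔS_Γ = -2Ωt [ avg(ȧ Φ'_ODE(a))/g_a* + avg(ḃ Φ'_ODE(b))/g_b* ],

with Φ'_ODE(a) = w+1 - w-1 and Φ'_ODE(b) = w-2 - w+2.  All functionals
use midpoint (Stratonovich) discretization, which assigns the
noise-gradient correlation its Stratonovich value.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np
from numba import njit

from .macroscopic import FixedPointSet, find_fixed_points, macroscopic_rates
from .params import SchloeglParams

__all__ = [
    "LangevinPath",
    "ActionBreakdown",
    "steady_state_setup",
    "simulate_langevin",
    "path_action",
    "path_entropy_production",
    "ensemble_entropy_production",
    "langevin_entropy_production",
    "weight_terms",
]


def _rates(x, a, b, p: SchloeglParams):
    """Vectorized channel rates with dynamic reservoir concentrations."""
    w_p1 = p.k_plus1 * a
    w_m1 = p.k_minus1 * x
    w_p2 = p.k_plus2 * x**3
    w_m2 = p.k_minus2 * b * x**2
    return w_p1, w_m1, w_p2, w_m2


def steady_state_setup(
    params: SchloeglParams, state: Literal["low", "high"] | float
) -> dict[str, float]:
    """Target fixed point, pinned flux F and frozen noise amplitudes.

    F is pinned to the target state's steady conversion flux
    w+1(x*) - w-1(x*), which makes (x*, a, b) a stationary point of the
    three-variable drift.
    """
    fps = find_fixed_points(params)
    stable = fps.stable_roots
    if isinstance(state, str):
        if state == "low":
            x_star = min(stable)
        elif state == "high":
            x_star = max(stable)
        else:
            raise ValueError("state must be 'low', 'high' or a concentration")
    else:
        x_star = float(state)
    w = macroscopic_rates(x_star, params)
    F = w.w_plus1 - w.w_minus1
    g_a = w.w_plus1 + w.w_minus1
    g_b = w.w_plus2 + w.w_minus2
    return {
        "x_star": x_star,
        "a_star": params.a_conc,
        "b_star": params.b_conc,
        "F": F,
        "g_a": g_a,
        "g_b": g_b,
        "g_x": g_a + g_b,
    }


@dataclasses.dataclass(frozen=True)
class LangevinPath:
    """Euler-Maruyama paths of the flux-constrained three-variable system.

    Arrays have shape (n_paths, n_steps + 1).  ``n_reflected`` counts
    negative-concentration excursions reflected at 0 (many reflections
    signal a breakdown of the additive-noise approximation).
    """

    t_grid: np.ndarray
    x: np.ndarray
    a: np.ndarray
    b: np.ndarray
    dt: float
    F: float
    g_a: float
    g_b: float
    eps: float
    seed: int
    n_reflected: int

    @property
    def g_x(self) -> float:
        return self.g_a + self.g_b

    @property
    def n_paths(self) -> int:
        return self.x.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t_grid[-1])


@njit(cache=True)
def _em_kernel(x, a, b, n_steps, dt, F, amp_a, amp_b,
               k_plus1, k_minus1, k_plus2, k_minus2, blowup, seed, clamp):
    np.random.seed(seed)
    n_paths = x.shape[0]
    n_reflected = 0
    for i in range(n_steps):
        for j in range(n_paths):
            xi, ai, bi = x[j, i], a[j, i], b[j, i]
            w_p1 = k_plus1 * ai
            w_m1 = k_minus1 * xi
            w_p2 = k_plus2 * xi**3
            w_m2 = k_minus2 * bi * xi**2
            za = amp_a * np.random.standard_normal()
            zb = amp_b * np.random.standard_normal()
            xn = xi + (w_p1 - w_m1 + w_m2 - w_p2) * dt - (za + zb)
            if clamp:
                an, bn = ai, bi
            else:
                an = ai + (-(w_p1 - w_m1) + F) * dt + za
                bn = bi + (-(w_m2 - w_p2) - F) * dt + zb
            if xn < 0 or an < 0 or bn < 0:
                n_reflected += 1
                xn = abs(xn)
                an = abs(an)
                bn = abs(bn)
            if abs(xn) > blowup:
                return -1
            x[j, i + 1], a[j, i + 1], b[j, i + 1] = xn, an, bn
    return n_reflected


def simulate_langevin(
    params: SchloeglParams,
    state: Literal["low", "high"] | float,
    eps: float | None = None,
    dt: float = 5e-4,
    t_max: float = 20.0,
    seed: int = 0,
    n_paths: int = 1,
    x0: tuple[float, float, float] | None = None,
    reflect_warn_frac: float = 1e-3,
    clamp_reservoirs: bool = False,
) -> LangevinPath:
    """Integrate the flux-constrained Langevin system near one steady state.

    Additive noise: η_a = sqrt(ε·g_a*)·ξ_a, η_b = sqrt(ε·g_b*)·ξ_b and
    η_x = -(η_a + η_b) (anticorrelated; no double counting of the
    reservoir noise).  ε defaults to 1/Ω.  A blow-up monitor raises if
    dt violates the stability of the drift.

    With ``clamp_reservoirs`` the reservoir concentrations a and b are
    held fixed (x keeps its anticorrelated noise): the one-variable
    chemical Langevin limit.  This is required for per-state ensembles
    of the LOW state, which the flux-pinned three-variable drift makes
    linearly unstable (the reservoir feedback selects the high state).
    """
    setup = steady_state_setup(params, state)
    if eps is None:
        eps = 1.0 / params.omega
    n_steps = int(round(t_max / dt))
    x = np.empty((n_paths, n_steps + 1))
    a = np.empty_like(x)
    bb = np.empty_like(x)
    if x0 is None:
        x0 = (setup["x_star"], setup["a_star"], setup["b_star"])
    x[:, 0], a[:, 0], bb[:, 0] = x0
    F = setup["F"]
    g_a, g_b = setup["g_a"], setup["g_b"]
    amp_a = math.sqrt(eps * g_a * dt)
    amp_b = math.sqrt(eps * g_b * dt)
    blowup = 10.0 * max(setup["x_star"], setup["a_star"], setup["b_star"], 1.0)
    n_reflected = _em_kernel(
        x, a, bb, n_steps, dt, F, amp_a, amp_b,
        params.k_plus1, params.k_minus1, params.k_plus2, params.k_minus2,
        blowup, seed, clamp_reservoirs,
    )
    if n_reflected < 0:
        raise RuntimeError(
            "Langevin integration blew up: reduce dt (stability violation)"
        )
    frac = n_reflected / (n_paths * n_steps * 3)
    if frac > reflect_warn_frac:
        import warnings

        warnings.warn(
            f"{frac:.2%} of steps reflected at zero concentration; "
            "additive-noise approximation is unreliable (raise omega)",
            RuntimeWarning,
        )
    return LangevinPath(
        t_grid=np.arange(n_steps + 1) * dt,
        x=x,
        a=a,
        b=bb,
        dt=dt,
        F=F,
        g_a=g_a,
        g_b=g_b,
        eps=eps,
        seed=seed,
        n_reflected=n_reflected,
    )


@njit(cache=True)
def _em_entropy_kernel(x0, a0, b0, n_steps, burn_steps, dt, F, amp_a, amp_b,
                       g_a, g_b, om, k_plus1, k_minus1, k_plus2, k_minus2,
                       blowup, seed, n_paths):
    """Integrate and accumulate the trajectory EP functional in O(1) memory.

    Returns per-path ΔS_Γ over the window after burn_steps, using the
    midpoint (Stratonovich) product of velocities and gradients.
    """
    np.random.seed(seed)
    dS = np.zeros(n_paths)
    ok = True
    for j in range(n_paths):
        xi, ai, bi = x0, a0, b0
        acc_a = 0.0
        acc_b = 0.0
        for i in range(n_steps):
            w_p1 = k_plus1 * ai
            w_m1 = k_minus1 * xi
            w_p2 = k_plus2 * xi**3
            w_m2 = k_minus2 * bi * xi**2
            za = amp_a * np.random.standard_normal()
            zb = amp_b * np.random.standard_normal()
            xn = xi + (w_p1 - w_m1 + w_m2 - w_p2) * dt - (za + zb)
            an = ai + (-(w_p1 - w_m1) + F) * dt + za
            bn = bi + (-(w_m2 - w_p2) - F) * dt + zb
            if xn < 0 or an < 0 or bn < 0:
                xn = abs(xn)
                an = abs(an)
                bn = abs(bn)
            if abs(xn) > blowup:
                ok = False
                break
            if i >= burn_steps:
                xm = 0.5 * (xi + xn)
                am = 0.5 * (ai + an)
                bm = 0.5 * (bi + bn)
                va = (an - ai) / dt
                vb = (bn - bi) / dt
                pha = k_plus1 * am - k_minus1 * xm
                phb = k_minus2 * bm * xm**2 - k_plus2 * xm**3
                acc_a += va * pha
                acc_b += vb * phb
            xi, ai, bi = xn, an, bn
        if not ok:
            dS[j] = np.nan
            break
        n_avg = n_steps - burn_steps
        t_eff = n_avg * dt
        dS[j] = -2.0 * om * t_eff * (
            acc_a / n_avg / g_a + acc_b / n_avg / g_b
        )
    return dS


def langevin_entropy_production(
    params: SchloeglParams,
    state: Literal["low", "high"] | float,
    eps: float | None = None,
    dt: float = 5e-4,
    t_max: float = 20.0,
    burn_in: float = 0.0,
    seed: int = 0,
    n_paths: int = 100,
) -> np.ndarray:
    """Per-path trajectory entropy production without storing paths.

    Streaming equivalent of ``simulate_langevin`` followed by
    ``path_entropy_production``; memory footprint is O(n_paths), which
    permits the long, finely resolved runs needed near equilibrium
    (the Stratonovich products carry an O(dt) integrator bias).
    """
    setup = steady_state_setup(params, state)
    if eps is None:
        eps = 1.0 / params.omega
    n_steps = int(round(t_max / dt))
    burn_steps = int(round(burn_in / dt))
    if burn_steps >= n_steps:
        raise ValueError("burn_in must be < t_max")
    amp_a = math.sqrt(eps * setup["g_a"] * dt)
    amp_b = math.sqrt(eps * setup["g_b"] * dt)
    blowup = 10.0 * max(setup["x_star"], setup["a_star"], setup["b_star"], 1.0)
    dS = _em_entropy_kernel(
        setup["x_star"], setup["a_star"], setup["b_star"],
        n_steps, burn_steps, dt, setup["F"], amp_a, amp_b,
        setup["g_a"], setup["g_b"], 1.0 / eps,
        params.k_plus1, params.k_minus1, params.k_plus2, params.k_minus2,
        blowup, seed, n_paths,
    )
    if np.isnan(dS).any():
        raise RuntimeError(
            "Langevin integration blew up: reduce dt (stability violation)"
        )
    return dS


def _midpoint_quantities(path: LangevinPath, params: SchloeglParams):
    """Midpoint values and finite-difference velocities per step."""
    xm = 0.5 * (path.x[:, 1:] + path.x[:, :-1])
    am = 0.5 * (path.a[:, 1:] + path.a[:, :-1])
    bm = 0.5 * (path.b[:, 1:] + path.b[:, :-1])
    vx = np.diff(path.x, axis=1) / path.dt
    va = np.diff(path.a, axis=1) / path.dt
    vb = np.diff(path.b, axis=1) / path.dt
    w_p1, w_m1, w_p2, w_m2 = _rates(xm, am, bm, params)
    # potential gradients read off the drift of each variable
    phi_x = -(w_p1 - w_m1 + w_m2 - w_p2)
    phi_a = w_p1 - w_m1
    phi_b = w_m2 - w_p2
    return (xm, am, bm), (vx, va, vb), (phi_x, phi_a, phi_b), (w_p1, w_m1, w_p2, w_m2)


@dataclasses.dataclass(frozen=True)
class ActionBreakdown:
    """Decomposition of the Onsager-Machlup action of one path.

    ``total`` = ``kinetic_potential`` + ``entropy_production`` + ``noise``
    holds exactly for the discretized functional; ``entropy_production``
    here includes the -F σ_q q̇ cross-term (whose time average vanishes
    at stationarity); ``ep_pure`` is the bare Ω Σ ∫ q̇ Φ'(q)/(g*)² form.
    """

    kinetic_potential: float
    entropy_production: float
    noise: float
    total: float
    ep_pure: float


def path_action(path: LangevinPath, params: SchloeglParams,
                path_index: int = 0) -> ActionBreakdown:
    """Discretized stochastic action of one path (midpoint rule).

    A = ∫ { Ω/2 Σ_q [q̇ + Φ'_ODE(q) - F σ_q]²/g_q* - ½ Σ_q Φ''_ODE(q) } dt

    with σ = (0, +1, -1) for q = (x, a, b); g_q* is the frozen noise
    variance scale, so the quadratic term is the exact Onsager-Machlup
    weight of the additive-noise system.
    """
    i = path_index
    om = 1.0 / path.eps if path.eps > 0 else params.omega
    dt = path.dt
    (xm, am, bm), (vx, va, vb), (phx, pha, phb), _ = _midpoint_quantities(path, params)
    xm, am, bm = xm[i], am[i], bm[i]
    vx, va, vb = vx[i], va[i], vb[i]
    phx, pha, phb = phx[i], pha[i], phb[i]
    g2 = {"x": path.g_x, "a": path.g_a, "b": path.g_b}
    sig = {"x": 0.0, "a": +1.0, "b": -1.0}
    # curvature of the per-variable potentials at midpoints
    curv_x = (3 * params.k_plus2 * xm**2 - 2 * params.k_minus2 * bm * xm
              + params.k_minus1)
    curv_a = np.full_like(am, params.k_plus1)
    curv_b = params.k_minus2 * xm**2
    kin_pot = 0.0
    ep = 0.0
    ep_pure = 0.0
    for v, ph, q in ((vx, phx, "x"), (va, pha, "a"), (vb, phb, "b")):
        force = ph - path.F * sig[q]
        kin_pot += om * np.sum(v**2 + force**2) * dt / (2 * g2[q])
        ep += om * np.sum(v * force) * dt / g2[q]
        ep_pure += om * np.sum(v * ph) * dt / g2[q]
    noise = -0.5 * np.sum(curv_x + curv_a + curv_b) * dt
    total = kin_pot + ep + noise
    return ActionBreakdown(
        kinetic_potential=float(kin_pot),
        entropy_production=float(ep),
        noise=float(noise),
        total=float(total),
        ep_pure=float(ep_pure),
    )


def path_entropy_production(
    path: LangevinPath, params: SchloeglParams, burn_in: float = 0.0
) -> np.ndarray:
    """Trajectory entropy production ΔS_Γ per path (k_B).

    ΔS_Γ = -2Ωt [avg(ȧ Φ'_ODE(a))/g_a* + avg(ḃ Φ'_ODE(b))/g_b*]
    over the stationary segment after ``burn_in``, with midpoint
    (Stratonovich) evaluation of the products; g* is the frozen noise
    variance scale of each reservoir.
    """
    if burn_in >= path.duration:
        raise ValueError("path shorter than burn_in")
    om = 1.0 / path.eps if path.eps > 0 else params.omega
    _, (vx, va, vb), (phx, pha, phb), _ = _midpoint_quantities(path, params)
    t_mid = 0.5 * (path.t_grid[1:] + path.t_grid[:-1])
    keep = t_mid >= burn_in
    t_eff = keep.sum() * path.dt
    avg_a = (va[:, keep] * pha[:, keep]).mean(axis=1)
    avg_b = (vb[:, keep] * phb[:, keep]).mean(axis=1)
    return -2.0 * om * t_eff * (avg_a / path.g_a + avg_b / path.g_b)


def ensemble_entropy_production(
    path: LangevinPath, params: SchloeglParams, burn_in: float = 0.0
) -> tuple[float, float]:
    """Ensemble mean and standard error of ΔS_Γ over the paths."""
    dS = path_entropy_production(path, params, burn_in)
    return float(dS.mean()), float(dS.std(ddof=1) / math.sqrt(len(dS)))


def weight_terms(
    paths_by_state: dict[str, LangevinPath],
    params: SchloeglParams,
    burn_in: float = 0.0,
) -> dict[str, dict[str, float]]:
    """Term-by-term structure of the steady-state weight per basin.

    For each basin ensemble: the classical-action density
    Σ_q [<q̇²> + <(Φ'_ODE(q) - Fσ_q)²>] / (2 g_q*) and the
    Schnakenberg entropy-production density
    ½ Σ_r <(w+r - w-r) ln(w+r/w-r)>, both per unit time, plus which
    state maximizes the EP term.  Mixed-basin ensembles (bimodal x
    samples straddling the ODE separatrix) are rejected.
    """
    fps = find_fixed_points(params)
    x_u = fps.unstable_root
    out: dict[str, dict[str, float]] = {}
    for name, path in paths_by_state.items():
        (xm, am, bm), (vx, va, vb), (phx, pha, phb), w = _midpoint_quantities(
            path, params
        )
        t_mid = 0.5 * (path.t_grid[1:] + path.t_grid[:-1])
        keep = t_mid >= burn_in
        xs = xm[:, keep]
        path_sel = np.ones(xs.shape[0], dtype=bool)
        if x_u is not None:
            # condition on non-switching paths: the per-state averages are
            # defined for rare switching only, so paths that escape their
            # basin are excluded; a majority-escaped ensemble is an error
            frac_low = (xs < x_u).mean(axis=1)
            target_low = frac_low.mean() > 0.5
            path_sel = frac_low > 0.98 if target_low else frac_low < 0.02
            if path_sel.sum() < max(2, len(path_sel) // 2):
                raise ValueError(
                    f"mixed-basin ensemble for state {name!r}: only "
                    f"{int(path_sel.sum())}/{len(path_sel)} paths stayed in "
                    "one basin"
                )
        xs = xs[path_sel]
        g2 = {"x": path.g_x, "a": path.g_a, "b": path.g_b}
        sig = {"x": 0.0, "a": +1.0, "b": -1.0}
        classical = 0.0
        for v, ph, q in (
            (vx[:, keep][path_sel], phx[:, keep][path_sel], "x"),
            (va[:, keep][path_sel], pha[:, keep][path_sel], "a"),
            (vb[:, keep][path_sel], phb[:, keep][path_sel], "b"),
        ):
            force = ph - path.F * sig[q]
            classical += (np.mean(v**2) + np.mean(force**2)) / (2 * g2[q])
        w_p1, w_m1, w_p2, w_m2 = (wi[:, keep][path_sel] for wi in w)
        with np.errstate(divide="ignore", invalid="ignore"):
            schnak = 0.5 * (
                np.mean((w_p1 - w_m1) * np.log(w_p1 / w_m1))
                + np.mean((w_p2 - w_m2) * np.log(w_p2 / w_m2))
            )
        out[name] = {
            "classical_action_rate": float(classical),
            "schnakenberg_rate": float(schnak),
        }
    if out:
        best = max(out, key=lambda k: out[k]["schnakenberg_rate"])
        for name in out:
            out[name]["max_ep_state"] = best
    return out
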