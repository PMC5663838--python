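"""Exact master-equation treatment of the Schlögl model.

The molecule number X performs a one-dimensional birth-death jump
process on {0, 1, 2, ...}.  Two reaction channels contribute to each
bond X <-> X+1:

* channel 1 (A <=> X): birth at constant propensity k+1·a·Ω,
  death at k-1·X;
* channel 2 (3X <=> 2X + B): birth at k-2·b·X(X-1)/Ω,
  death at k+2·X(X-1)(X-2)/Ω².

Because the chain is nearest-neighbour and reflecting at 0, the
stationary distribution obeys a zero-net-flux recursion across each
bond, which is evaluated in log space.  Entropy flow and production
rates, their per-state decomposition at the separatrix, the critical
driving b_c, and exact mean first-passage times are all computed from
these propensities.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.sparse.linalg import expm_multiply

from .macroscopic import find_fixed_points
from .params import SchloeglParams

__all__ = [
    "StationaryDistribution",
    "StatePartition",
    "TransientSolution",
    "micro_propensities",
    "propensity_arrays",
    "stationary_distribution",
    "generator_matrix",
    "evolve_distribution",
    "entropy_rates",
    "shannon_entropy",
    "per_state_ep_contributions",
    "partition_states",
    "state_ep_delta_approx",
    "critical_b",
    "exact_mfpt",
]


# --------------------------------------------------------------------------
# propensities
# --------------------------------------------------------------------------

def micro_propensities(
    X: int, params: SchloeglParams
) -> tuple[float, float, float, float]:
    """Propensities of the four reaction events out of state X.

    Returns (W_plus1, W_minus1, W_plus2, W_minus2):
    W_plus1  = k+1·a·Ω            (X -> X+1, channel 1)
    W_minus1 = k-1·X              (X -> X-1, channel 1)
    W_plus2  = k+2·X(X-1)(X-2)/Ω² (X -> X-1, channel 2)
    W_minus2 = k-2·b·X(X-1)/Ω     (X -> X+1, channel 2)
    """
    if X < 0:
        raise ValueError("molecule number must be >= 0")
    om = params.omega
    return (
        params.k1a * om,
        params.k_minus1 * X,
        params.k_plus2 * X * (X - 1) * (X - 2) / om**2,
        params.k_minus2 * params.b_conc * X * (X - 1) / om,
    )


def propensity_arrays(
    x_max: int, params: SchloeglParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized propensities (W+1, W-1, W+2, W-2) for X = 0..x_max."""
    X = np.arange(x_max + 1, dtype=float)
    om = params.omega
    w_p1 = np.full_like(X, params.k1a * om)
    w_m1 = params.k_minus1 * X
    w_p2 = params.k_plus2 * X * (X - 1) * (X - 2) / om**2
    w_m2 = params.k_minus2 * params.b_conc * X * (X - 1) / om
    return w_p1, w_m1, w_p2, w_m2


# --------------------------------------------------------------------------
# stationary distribution
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class StationaryDistribution:
    """Stationary pmf of the truncated birth-death chain."""

    omega: float
    x_max: int
    pmf: np.ndarray
    tail_mass_bound: float

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.x_max + 1)

    @property
    def x_grid(self) -> np.ndarray:
        """Concentration grid X/Ω."""
        return self.support / self.omega

    def mean_concentration(self) -> float:
        return float(np.dot(self.support, self.pmf)) / self.omega


def _auto_x_max(params: SchloeglParams) -> int:
    fps = find_fixed_points(params)
    x_high = max(fps.roots) if fps.roots else 1.0
    return int(max(8 * params.omega * max(x_high, 0.5), 50))


def stationary_distribution(
    params: SchloeglParams, x_max: int | None = None
) -> StationaryDistribution:
    """Exact stationary pmf via the zero-net-flux bond recursion.

    For a reflecting nearest-neighbour chain the stationary state has
    zero net probability flux across every bond:

        [W+1 + W-2](X) P(X) = [W-1 + W+2](X+1) P(X+1).

    The log of the recursion is accumulated and exponentiated after
    subtracting the maximum, then normalized.  With automatic
    truncation the support is grown geometrically until the tail bound
    (a geometric-series bound on the discarded mass using the terminal
    birth/death ratio) falls below 1e-10.
    """
    hard_cap = int(50 * params.omega) + 200
    if x_max is not None:
        pmf, tail = _stationary_on(params, x_max)
        return StationaryDistribution(params.omega, x_max, pmf, tail)
    m = _auto_x_max(params)
    while True:
        pmf, tail = _stationary_on(params, m)
        if tail < 1e-10:
            return StationaryDistribution(params.omega, m, pmf, tail)
        if m >= hard_cap:
            raise RuntimeError(
                f"no decaying tail found before truncation cap {hard_cap}"
            )
        m = min(2 * m, hard_cap)


def _stationary_on(params: SchloeglParams, x_max: int) -> tuple[np.ndarray, float]:
    w_p1, w_m1, w_p2, w_m2 = propensity_arrays(x_max + 1, params)
    birth = w_p1 + w_m2  # out of X, X -> X+1
    death = w_m1 + w_p2  # out of X, X -> X-1
    with np.errstate(divide="ignore"):
        log_ratio = np.log(birth[:-2]) - np.log(death[1:-1])
    logp = np.concatenate([[0.0], np.cumsum(log_ratio)])
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    # geometric bound on the truncated mass: beyond x_max the ratio
    # birth/death keeps decreasing (death grows cubically), so
    # P(x_max + j) <= P(x_max) * rho^j with rho at the boundary.
    rho = birth[x_max] / death[x_max + 1]
    tail = pmf[-1] * rho / (1.0 - rho) if rho < 1.0 else np.inf
    return pmf, float(tail)


# --------------------------------------------------------------------------
# generator and transient dynamics
# --------------------------------------------------------------------------

def generator_matrix(params: SchloeglParams, x_max: int) -> sp.csc_matrix:
    """Sparse master-equation generator Q with dP/dt = Q P on 0..x_max.

    The chain is reflecting at both ends (birth out of x_max removed).
    """
    w_p1, w_m1, w_p2, w_m2 = propensity_arrays(x_max, params)
    birth = w_p1 + w_m2
    death = w_m1 + w_p2
    birth = birth.copy()
    birth[-1] = 0.0  # reflecting upper boundary
    diag = -(birth + death)
    lower = birth[:-1]  # flow X -> X+1
    upper = death[1:]  # flow X+1 -> X
    return sp.diags(
        [lower, diag, upper], offsets=[-1, 0, 1], format="csc"
    )


def shannon_entropy(pmf: np.ndarray) -> float:
    """Gibbs-Boltzmann entropy -Σ P ln P in k_B (0·ln 0 := 0).

    Internal molecular entropies S0(X) are taken as zero throughout, so
    this distribution term is the full entropy.
    """
    p = np.asarray(pmf, dtype=float)
    mask = p > 0
    return float(-np.sum(p[mask] * np.log(p[mask])))


@dataclasses.dataclass(frozen=True)
class TransientSolution:
    """Time-dependent solution of the master equation with entropy bookkeeping."""

    t_grid: np.ndarray
    pmf_t: np.ndarray  # shape (n_times, n_states)
    entropy: np.ndarray  # S(t), k_B
    dsi_dt: np.ndarray  # entropy production rate, k_B/time
    dse_dt: np.ndarray  # entropy flow rate, k_B/time


def evolve_distribution(
    P0: np.ndarray,
    t_grid: Sequence[float],
    params: SchloeglParams,
    method: Literal["expm", "bdf"] = "expm",
) -> TransientSolution:
    """Propagate dP/dt = Q P and record entropy rates along the way.

    The default propagator is the Krylov matrix exponential, exact to
    machine precision for this linear (stiff) system; a BDF integrator
    with tight tolerances is available as a cross-check.
    """
    P0 = np.asarray(P0, dtype=float)
    if abs(P0.sum() - 1.0) > 1e-8 or (P0 < -1e-12).any():
        raise ValueError("P0 must be a normalized pmf on the truncated support")
    t_grid = np.asarray(list(t_grid), dtype=float)
    Q = generator_matrix(params, len(P0) - 1)
    if method == "expm":
        pmf_t = np.empty((len(t_grid), len(P0)))
        # expm_multiply wants a uniform grid; do each time from t=0 instead
        for i, t in enumerate(t_grid):
            if t == 0.0:
                pmf_t[i] = P0
            else:
                pmf_t[i] = expm_multiply(Q * t, P0)
    elif method == "bdf":
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda _, p: Q @ p,
            (0.0, float(t_grid.max())),
            P0,
            t_eval=t_grid,
            method="BDF",
            rtol=1e-9,
            atol=1e-12,
            jac=lambda _, __: Q,
        )
        pmf_t = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")
    pmf_t = np.clip(pmf_t, 0.0, None)
    pmf_t /= pmf_t.sum(axis=1, keepdims=True)
    S = np.array([shannon_entropy(p) for p in pmf_t])
    rates = np.array([entropy_rates(p, params) for p in pmf_t])
    return TransientSolution(t_grid, pmf_t, S, rates[:, 0], rates[:, 1])


# --------------------------------------------------------------------------
# entropy rates
# --------------------------------------------------------------------------

def _bond_quantities(P: np.ndarray, params: SchloeglParams):
    """Per-bond per-channel fluxes and log rate ratios.

    For each bond X -> X+1 and each channel c, the forward (birth) rate
    out of X and backward (death) rate out of X+1.
    """
    n = len(P) - 1
    w_p1, w_m1, w_p2, w_m2 = propensity_arrays(len(P) - 1, params)
    fwd = np.stack([w_p1[:-1], w_m2[:-1]])  # channel 1, channel 2 births at X
    bwd = np.stack([w_m1[1:], w_p2[1:]])  # deaths at X+1
    return fwd, bwd


def entropy_rates(P: np.ndarray, params: SchloeglParams) -> tuple[float, float]:
    """Entropy production and flow rates (dSi_dt, dSe_dt) in k_B/time.

    Summing over every bond and channel once (which absorbs the factor
    1/2 that compensates double counting of forward/backward pairs):

        dSi/dt = Σ (J_c ln[(W_fwd P(X)) / (W_bwd P(X+1))])  >= 0
        dSe/dt = -Σ (J_c ln[W_fwd / W_bwd])

    with J_c = W_fwd P(X) - W_bwd P(X+1) the net channel flux across the
    bond.  Terms with vanishing occupancy on both sides contribute 0.
    """
    P = np.asarray(P, dtype=float)
    fwd, bwd = _bond_quantities(P, params)
    a = fwd * P[:-1]  # forward probability flux
    b = bwd * P[1:]  # backward probability flux
    J = a - b
    both = (a > 0) & (b > 0)
    dsi = float(np.sum(J[both] * (np.log(a[both]) - np.log(b[both]))))
    # one-sided fluxes (P zero on one side) contribute infinitely in
    # principle; they are omitted, consistent with 0·ln 0 := 0 for the
    # vanishing side and relevant only for singular initial conditions.
    ok = (fwd > 0) & (bwd > 0)
    dse = -float(np.sum(J[ok & (a + b > 0)] * (np.log(fwd[ok & (a + b > 0)]) - np.log(bwd[ok & (a + b > 0)]))))
    return dsi, dse


def per_state_ep_contributions(P: np.ndarray, params: SchloeglParams) -> np.ndarray:
    """Stationary entropy production assigned per source state X.

    Each reaction event out of X contributes W_ev(X)·P(X)·ln(W_ev/W_rev)
    with W_rev the reverse rate of the same channel at the target state.
    Summed over all X this equals -dSe/dt, which at stationarity equals
    the entropy production rate, so the per-state pieces decompose the
    total exactly.
    """
    P = np.asarray(P, dtype=float)
    n = len(P)
    w_p1, w_m1, w_p2, w_m2 = propensity_arrays(n - 1, params)
    contrib = np.zeros(n)

    def add(rate_out, rate_back, shift):
        # event X -> X+shift with forward rate rate_out[X] and reverse
        # rate rate_back evaluated at the target X+shift
        if shift == +1:
            src = slice(0, n - 1)
            r_f = rate_out[:-1]
            r_b = rate_back[1:]
        else:
            src = slice(1, n)
            r_f = rate_out[1:]
            r_b = rate_back[:-1]
        ok = (r_f > 0) & (r_b > 0)
        term = np.zeros(n - 1)
        term[ok] = r_f[ok] * np.log(r_f[ok] / r_b[ok])
        contrib[src] += term * P[src]

    add(w_p1, w_m1, +1)  # channel-1 birth vs channel-1 death
    add(w_m1, w_p1, -1)
    add(w_m2, w_p2, +1)  # channel-2 birth vs channel-2 death
    add(w_p2, w_m2, -1)
    return contrib


# --------------------------------------------------------------------------
# state partition at the separatrix
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class StatePartition:
    """Separatrix location and per-state weights / EP rates.

    For a bimodal stationary pmf the separatrix is the interior local
    minimum between the two dominant modes; weights, mean concentrations
    and extensive entropy production rates dS_{i,k}/dt are accumulated on
    each side, with the separatrix bin split 50/50.
    """

    separatrix_X: int | None
    separatrix_x: float | None
    weights: tuple[float, ...]
    means: tuple[float, ...]
    ep_rates: tuple[float, ...]

    @property
    def bimodal(self) -> bool:
        return self.separatrix_X is not None


def _log_pmf_extrema(pmf: np.ndarray) -> tuple[list[int], list[int]]:
    """Interior maxima and minima of the (3-point smoothed) log pmf."""
    with np.errstate(divide="ignore"):
        logp = np.log(pmf)
    # 3-point moving maximum suppresses single-bin noise at small Ω
    sm = logp.copy()
    sm[1:-1] = np.maximum(np.maximum(logp[:-2], logp[1:-1]), logp[2:])
    maxima, minima = [], []
    for i in range(1, len(sm) - 1):
        if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1]:
            maxima.append(i)
        if sm[i] < sm[i - 1] and sm[i] <= sm[i + 1] and np.isfinite(sm[i]):
            minima.append(i)
    # include boundary mode at 0
    if len(sm) > 1 and sm[0] > sm[1]:
        maxima.insert(0, 0)
    return maxima, minima


def partition_states(
    P: StationaryDistribution, params: SchloeglParams
) -> StatePartition:
    """Split the stationary pmf at the separatrix into low/high states.

    Unimodal distributions return a single state of weight 1.  The
    entropy production of each state restricts the per-state (source-X)
    decomposition of the stationary EP to each side of the separatrix,
    the separatrix bin itself counting half toward each state.
    """
    pmf = P.pmf
    maxima, _ = _log_pmf_extrema(pmf)
    # keep the two largest modes
    maxima = sorted(sorted(maxima, key=lambda i: -pmf[i])[:2])
    X = P.support
    ep = per_state_ep_contributions(pmf, params)
    if len(maxima) < 2:
        return StatePartition(
            separatrix_X=None,
            separatrix_x=None,
            weights=(1.0,),
            means=(P.mean_concentration(),),
            ep_rates=(float(ep.sum()),),
        )
    lo, hi = maxima
    interior = np.arange(lo + 1, hi)
    if len(interior) == 0:
        raise ValueError("ambiguous partition: adjacent modes")
    s = int(interior[np.argmin(pmf[interior])])
    w_low = pmf[:s].sum() + 0.5 * pmf[s]
    w_high = pmf[s + 1 :].sum() + 0.5 * pmf[s]
    m_low = (np.dot(X[:s], pmf[:s]) + 0.5 * s * pmf[s]) / w_low / P.omega
    m_high = (np.dot(X[s + 1 :], pmf[s + 1 :]) + 0.5 * s * pmf[s]) / w_high / P.omega
    ep_low = ep[:s].sum() + 0.5 * ep[s]
    ep_high = ep[s + 1 :].sum() + 0.5 * ep[s]
    return StatePartition(
        separatrix_X=s,
        separatrix_x=s / P.omega,
        weights=(float(w_low), float(w_high)),
        means=(float(m_low), float(m_high)),
        ep_rates=(float(ep_low), float(ep_high)),
    )


def state_ep_delta_approx(
    params: SchloeglParams,
    P: StationaryDistribution,
    fixed_points,
) -> tuple[float, float]:
    """Per-state extensive EP rates from the δ-peak approximation.

    Each peak k is collapsed onto its macroscopic fixed point x_k*, so
    dS_{i,k}/dt = N p(x_k*) Ω ds_{i,k}/dt with ds_{i,k}/dt the
    macroscopic (Schnakenberg) rate at x_k* and N p(x_k*) the relative
    peak height of the stationary pmf (N normalizing the two heights).
    """
    from .macroscopic import macroscopic_entropy_production

    stable = fixed_points.stable_roots
    if len(stable) != 2:
        raise ValueError("delta approximation requires bistable parameters")
    heights = []
    for x_star in stable:
        Xs = int(round(x_star * P.omega))
        lo, hi = max(Xs - 2, 0), min(Xs + 3, len(P.pmf))
        heights.append(P.pmf[lo:hi].max())
    N = 1.0 / (heights[0] + heights[1])
    out = []
    for x_star, h in zip(stable, heights):
        dsi, _, _ = macroscopic_entropy_production(x_star, params)
        out.append(N * h * P.omega * dsi)
    return tuple(out)


# --------------------------------------------------------------------------
# critical driving
# --------------------------------------------------------------------------

def _weight_diff(b: float, params: SchloeglParams) -> float:
    p = stationary_distribution(params.with_(b_conc=b))
    part = partition_states(p, params.with_(b_conc=b))
    if not part.bimodal:
        # monostable: all mass on one branch; the branches are separated
        # by the unstable root band (roughly x = 1 for these rates)
        fps = find_fixed_points(params.with_(b_conc=b))
        gap = fps.unstable_root
        if gap is None:
            gap = 0.5 * (params.k1a / params.k_minus1
                         + params.k_minus2 * max(b, 1e-12) / params.k_plus2)
        return 1.0 if p.mean_concentration() < gap else -1.0
    return part.weights[0] - part.weights[1]


def _ep_diff(b: float, params: SchloeglParams) -> float:
    p = stationary_distribution(params.with_(b_conc=b))
    part = partition_states(p, params.with_(b_conc=b))
    if not part.bimodal:
        # effectively all mass (and hence all extensive EP) in one state
        return _weight_diff(b, params)
    return part.ep_rates[0] - part.ep_rates[1]


def critical_b(
    params: SchloeglParams,
    bracket: tuple[float, float] = (3.3, 3.9),
    xtol: float = 1e-4,
) -> dict[str, float]:
    """Critical driving strengths from the exact stationary pmf.

    Returns ``b_weight``: the b at which the low- and high-state
    probability weights cross (the first-order transition point), and
    ``b_ep``: the b at which the two extensive per-state entropy
    production rates cross.  The two are close but need not coincide.
    """
    lo, hi = bracket
    f_lo, f_hi = _weight_diff(lo, params), _weight_diff(hi, params)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no weight crossing in bracket {bracket}: f({lo})={f_lo:.3g}, "
            f"f({hi})={f_hi:.3g}"
        )
    b_w = brentq(_weight_diff, lo, hi, args=(params,), xtol=xtol)
    try:
        b_e = brentq(_ep_diff, lo, hi, args=(params,), xtol=xtol)
    except ValueError:
        b_e = np.nan
    return {"b_weight": float(b_w), "b_ep": float(b_e)}


# --------------------------------------------------------------------------
# mean first-passage times
# --------------------------------------------------------------------------

def exact_mfpt(params: SchloeglParams, from_X: int, to_X: int,
               x_max: int | None = None) -> float:
    """Exact mean first-passage time between molecule numbers.

    Uses the standard nested-sum formula for a birth-death chain with
    the unnormalized stationary measure π (log-space): for an upward
    passage i -> j,

        T = Σ_{z=i}^{j-1} 1/(B(z) π(z)) Σ_{y<=z} π(y),

    and the mirror formula downward, with the chain reflecting at 0 and
    at the truncation bound.
    """
    if from_X == to_X:
        raise ValueError("from_X and to_X must differ")
    m = x_max if x_max is not None else _auto_x_max(params)
    m = max(m, from_X + 5, to_X + 5)
    w_p1, w_m1, w_p2, w_m2 = propensity_arrays(m, params)
    B = w_p1 + w_m2
    D = w_m1 + w_p2
    B[-1] = 0.0
    with np.errstate(divide="ignore"):
        log_ratio = np.log(B[:-1]) - np.log(D[1:])
    logpi = np.concatenate([[0.0], np.cumsum(log_ratio)])
    # log-space running sums keep extremely skewed measures finite
    if from_X < to_X:
        zs = np.arange(from_X, to_X)
        if np.any(B[zs] == 0):
            raise ValueError("target unreachable: zero birth rate on path")
        log_cum = np.logaddexp.accumulate(logpi)
        terms = log_cum[zs] - logpi[zs] - np.log(B[zs])
        return float(np.exp(terms).sum())
    zs = np.arange(to_X + 1, from_X + 1)
    if np.any(D[zs] == 0):
        raise ValueError("target unreachable: zero death rate on path")
    log_cum_rev = np.logaddexp.accumulate(logpi[::-1])[::-1]
    terms = log_cum_rev[zs] - logpi[zs] - np.log(D[zs])
    return float(np.exp(terms).sum())
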