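"""Macroscopic (deterministic) treatment of the Schlögl model.

Rate laws, the deterministic ODE dx/dt = -Φ'_ODE(x), its fixed points
and their stability, the bifurcation structure in the driving b, and
the macroscopic entropy production rate (Schnakenberg form)

    ds_i/dt = Σ_r (w_{+r} - w_{-r}) ln(w_{+r}/w_{-r})  >= 0,

in units of k_B per volume per time.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .params import SchloeglParams

__all__ = [
    "ChannelRates",
    "FixedPointSet",
    "macroscopic_rates",
    "ode_drift",
    "find_fixed_points",
    "bifurcation_sweep",
    "equilibrium_point",
    "macroscopic_entropy_production",
]

# roots with relative imaginary part above this are discarded as complex
_IMAG_TOL = 1e-9
# double-root (saddle-node) classification threshold on the curvature
_MARGINAL_TOL = 1e-7


@dataclasses.dataclass(frozen=True)
class ChannelRates:
    """Macroscopic reaction rates of the four channels at a concentration x."""

    w_plus1: float
    w_minus1: float
    w_plus2: float
    w_minus2: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_plus1, self.w_minus1, self.w_plus2, self.w_minus2)


@dataclasses.dataclass(frozen=True)
class FixedPointSet:
    """Real nonnegative steady states of the deterministic ODE, ascending.

    ``stability`` entries are "stable", "unstable" or "marginal"
    (saddle-node double root).  ``curvature_ode`` is Φ''_ODE(x*), positive
    at stable states.  ``flux`` is the steady-state conversion flux
    F = w+1 - w-1 (= w+2 - w-2 at a fixed point).
    """

    roots: tuple[float, ...]
    stability: tuple[str, ...]
    curvature_ode: tuple[float, ...]
    flux: tuple[float, ...]

    @property
    def bistable(self) -> bool:
        return self.stability.count("stable") == 2

    @property
    def stable_roots(self) -> tuple[float, ...]:
        return tuple(r for r, s in zip(self.roots, self.stability) if s == "stable")

    @property
    def unstable_root(self) -> float | None:
        for r, s in zip(self.roots, self.stability):
            if s == "unstable":
                return r
        return None


def macroscopic_rates(x: float, params: SchloeglParams) -> ChannelRates:
    """Evaluate the four mass-action rate laws at concentration x.

    w+1 = k+1 a, w-1 = k-1 x, w+2 = k+2 x^3, w-2 = k-2 b x^2.
    """
    if x < 0:
        raise ValueError(f"concentration must be >= 0, got {x}")
    return ChannelRates(
        w_plus1=params.k1a,
        w_minus1=params.k_minus1 * x,
        w_plus2=params.k_plus2 * x**3,
        w_minus2=params.k_minus2 * params.b_conc * x**2,
    )


def ode_drift(x: float, params: SchloeglParams) -> tuple[float, float, float]:
    """Drift dx/dt and the effective-potential derivatives at x.

    Returns (drift, phi1_ode, phi2_ode) where phi1_ode = Φ'_ODE(x) = -drift
    and phi2_ode = Φ''_ODE(x) = 3 k+2 x^2 - 2 k-2 b x + k-1.
    """
    w = macroscopic_rates(x, params)
    drift = w.w_plus1 - w.w_minus1 + w.w_minus2 - w.w_plus2
    phi2 = (
        3.0 * params.k_plus2 * x**2
        - 2.0 * params.k_minus2 * params.b_conc * x
        + params.k_minus1
    )
    return drift, -drift, phi2


def _cubic_roots(params: SchloeglParams) -> list[float]:
    # drift = -k+2 x^3 + k-2 b x^2 - k-1 x + k+1 a = 0
    coeffs = [
        -params.k_plus2,
        params.k_minus2 * params.b_conc,
        -params.k_minus1,
        params.k1a,
    ]
    if params.k_plus2 == 0:
        coeffs = coeffs[1:]
        if params.k_minus2 * params.b_conc == 0:
            coeffs = coeffs[1:]
    roots = np.roots(coeffs)
    real: list[float] = []
    for z in roots:
        if abs(z.imag) <= _IMAG_TOL * max(1.0, abs(z.real)):
            real.append(max(z.real, 0.0))
    return sorted(real)


def find_fixed_points(params: SchloeglParams) -> FixedPointSet:
    """All real nonnegative fixed points of the deterministic ODE.

    Stability follows the sign of Φ''_ODE at the root; a (numerically)
    vanishing curvature is classified as "marginal" (saddle-node).
    """
    roots = _cubic_roots(params)
    # collapse near-coincident roots from a saddle-node
    merged: list[float] = []
    for r in roots:
        if merged and abs(r - merged[-1]) < 1e-9 * max(1.0, abs(r)):
            continue
        merged.append(r)
    stability, curvature, flux = [], [], []
    scale = max(1.0, params.k_minus1, params.k_minus2 * params.b_conc)
    for r in merged:
        _, _, phi2 = ode_drift(r, params)
        if abs(phi2) < _MARGINAL_TOL * scale:
            stability.append("marginal")
        elif phi2 > 0:
            stability.append("stable")
        else:
            stability.append("unstable")
        curvature.append(phi2)
        w = macroscopic_rates(r, params)
        flux.append(w.w_plus1 - w.w_minus1)
    return FixedPointSet(
        roots=tuple(merged),
        stability=tuple(stability),
        curvature_ode=tuple(curvature),
        flux=tuple(flux),
    )


def bifurcation_sweep(
    b_grid: Sequence[float], params: SchloeglParams
) -> list[FixedPointSet]:
    """Fixed points for every b in the grid (other parameters fixed)."""
    if len(b_grid) == 0:
        raise ValueError("b_grid must be nonempty")
    if any(b < 0 for b in b_grid):
        raise ValueError("b values must be >= 0")
    return [find_fixed_points(params.with_(b_conc=b)) for b in b_grid]


def equilibrium_point(params: SchloeglParams) -> tuple[float, float]:
    """The detailed-balance point (b0, x0) of the network.

    x0 = k+1 a / k-1 and b0 = k+2 x0 / k-2; there every channel satisfies
    w+r = w-r and the entropy production vanishes.
    """
    if params.k_minus1 == 0 or params.k_minus2 == 0:
        raise ValueError("degenerate model: k_minus1 and k_minus2 must be > 0")
    x0 = params.k1a / params.k_minus1
    b0 = params.k_plus2 * x0 / params.k_minus2
    return b0, x0


def macroscopic_entropy_production(
    x: float, params: SchloeglParams
) -> tuple[float, tuple[float, float], float]:
    """Schnakenberg entropy production rate at concentration x.

    Returns (dsi_dt, (term_channel1, term_channel2), flux) with
    dsi_dt = Σ_r (w+r - w-r) ln(w+r/w-r) in k_B/(volume·time) and
    flux = w+1 - w-1.  A channel with one vanishing rate but a nonzero
    partner has infinite affinity; the term is reported as +inf rather
    than raising, so sweeps through x = 0 do not abort.
    """
    w = macroscopic_rates(x, params)
    terms = []
    for plus, minus in ((w.w_plus1, w.w_minus1), (w.w_plus2, w.w_minus2)):
        if plus == 0.0 and minus == 0.0:
            terms.append(0.0)
        elif plus == 0.0 or minus == 0.0:
            terms.append(math.inf)
        else:
            terms.append((plus - minus) * math.log(plus / minus))
    return terms[0] + terms[1], (terms[0], terms[1]), w.w_plus1 - w.w_minus1
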