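"""Large-volume (WKB) analysis of the Schlögl stationary distribution.

For large Ω the stationary density takes the eikonal form
p(x) ∝ N(x) exp(-Ω Φ(x)) with the nonequilibrium potential Φ obtained
from the birth-death structure of the chain:

    Φ'(x) = ln[(w-1(x) + w+2(x)) / (w+1(x) + w-2(x))],

the log-ratio of the total death to total birth rate per volume.  Φ' is
zero exactly at the deterministic fixed points, reduces to the
detailed-balance potential at b = b0, and reproduces the continuum
limit of the exact stationary recursion.  Two prefactor conventions are
supported: the standard birth-death N(x) ∝ [(w+1+w-2)(w-1+w+2)]^{-1/2}
and a constant prefactor (peak-height approximation).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np
from scipy.integrate import quad

from .macroscopic import FixedPointSet, find_fixed_points
from .params import SchloeglParams

__all__ = [
    "WKBPotential",
    "GaussianPeakModel",
    "phi_prime",
    "phi_double_prime",
    "compute_potential",
    "wkb_density",
    "gaussian_peaks",
    "escape_rate_ratio",
]

PrefactorMode = Literal["constant", "birth-death-standard"]


def _birth_death_conc(x: np.ndarray | float, params: SchloeglParams):
    """Per-volume total birth and death rates at concentration x."""
    birth = params.k1a + params.k_minus2 * params.b_conc * np.asarray(x) ** 2
    death = params.k_minus1 * np.asarray(x) + params.k_plus2 * np.asarray(x) ** 3
    return birth, death


def phi_prime(x: np.ndarray | float, params: SchloeglParams) -> np.ndarray | float:
    """Derivative Φ'(x) = ln(death/birth) of the WKB potential."""
    birth, death = _birth_death_conc(x, params)
    with np.errstate(divide="ignore"):
        return np.log(death) - np.log(birth)


def phi_double_prime(x: np.ndarray | float, params: SchloeglParams):
    """Analytic curvature Φ''(x) = D'(x)/D(x) - B'(x)/B(x)."""
    x = np.asarray(x, dtype=float)
    birth, death = _birth_death_conc(x, params)
    d_birth = 2.0 * params.k_minus2 * params.b_conc * x
    d_death = params.k_minus1 + 3.0 * params.k_plus2 * x**2
    return d_death / death - d_birth / birth


@dataclasses.dataclass(frozen=True)
class WKBPotential:
    """The nonequilibrium potential Φ on a concentration grid."""

    x_grid: np.ndarray
    phi: np.ndarray
    fixed_points: FixedPointSet
    phi_at_fp: tuple[float, ...]  # Φ at each fixed point (same order as roots)
    phi2_at_fp: tuple[float, ...]  # Φ''(x*) at each fixed point
    prefactor_mode: PrefactorMode
    params: SchloeglParams

    def phi_at(self, x: float) -> float:
        """Φ(x) by adaptive quadrature from the reference point."""
        x_ref = self._x_ref()
        val, _ = quad(lambda s: phi_prime(s, self.params), x_ref, x,
                      epsabs=1e-10, limit=200)
        return float(val)

    def _x_ref(self) -> float:
        stable = self.fixed_points.stable_roots
        return min(stable) if stable else self.fixed_points.roots[0]


def compute_potential(
    params: SchloeglParams,
    x_grid: np.ndarray,
    prefactor_mode: PrefactorMode = "birth-death-standard",
) -> WKBPotential:
    """Integrate Φ' over the grid, anchored at the smallest stable fixed point.

    Φ is accumulated by adaptive quadrature between consecutive grid
    points (absolute tolerance 1e-10 per segment); Φ'' is analytic.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.ndim != 1 or len(x_grid) < 2 or np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must be 1D, increasing, length >= 2")
    if x_grid[0] < 0:
        raise ValueError("x_grid must be nonnegative")
    fps = find_fixed_points(params)
    if fps.roots and (x_grid[0] > min(fps.roots) or x_grid[-1] < max(fps.roots)):
        raise ValueError("x_grid must cover all fixed points")
    # segment-wise quadrature, then anchor at the reference point
    seg = np.empty(len(x_grid))
    seg[0] = 0.0
    for i in range(1, len(x_grid)):
        val, _ = quad(lambda s: phi_prime(s, params), x_grid[i - 1], x_grid[i],
                      epsabs=1e-10, limit=100)
        seg[i] = val
    phi = np.cumsum(seg)
    stable = [r for r, s in zip(fps.roots, fps.stability) if s == "stable"]
    x_ref = min(stable) if stable else fps.roots[0]
    phi_ref = float(np.interp(x_ref, x_grid, phi))
    phi -= phi_ref
    phi_at_fp = tuple(float(np.interp(r, x_grid, phi)) for r in fps.roots)
    phi2_at_fp = tuple(float(phi_double_prime(r, params)) for r in fps.roots)
    return WKBPotential(
        x_grid=x_grid,
        phi=phi,
        fixed_points=fps,
        phi_at_fp=phi_at_fp,
        phi2_at_fp=phi2_at_fp,
        prefactor_mode=prefactor_mode,
        params=params,
    )


def wkb_density(pot: WKBPotential, omega: float) -> np.ndarray:
    """Approximate stationary density N(x)·exp(-ΩΦ(x)), normalized on the grid."""
    log_dens = -omega * pot.phi
    if pot.prefactor_mode == "birth-death-standard":
        birth, death = _birth_death_conc(pot.x_grid, pot.params)
        with np.errstate(divide="ignore"):
            log_pref = -0.5 * (np.log(birth) + np.log(death))
        log_pref[~np.isfinite(log_pref)] = -np.inf
        log_dens = log_dens + log_pref
    log_dens -= np.max(log_dens[np.isfinite(log_dens)])
    dens = np.exp(log_dens)
    norm = np.trapezoid(dens, pot.x_grid)
    return dens / norm


@dataclasses.dataclass(frozen=True)
class GaussianPeakModel:
    """Gaussian expansion of the stationary density around the stable states.

    Peak k has center x_k*, standard deviation 1/sqrt(Ω Φ''(x_k*)) and
    weight N p(x_k*), the relative density at the fixed point.
    """

    centers: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    omega: float

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c, sd, w in zip(self.centers, self.sds, self.weights):
            out += w * np.exp(-0.5 * ((x - c) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        return out


def gaussian_peaks(
    pot: WKBPotential, params: SchloeglParams, omega: float
) -> GaussianPeakModel:
    """Two-Gaussian approximation of the bimodal stationary density."""
    stable = pot.fixed_points.stable_roots
    if len(stable) != 2:
        raise ValueError("Gaussian peak model requires bistable parameters")
    dens = wkb_density(pot, omega)
    heights = tuple(float(np.interp(r, pot.x_grid, dens)) for r in stable)
    N = 1.0 / (heights[0] + heights[1])
    phi2 = tuple(float(phi_double_prime(r, params)) for r in stable)
    if min(phi2) <= 0:
        raise ValueError("Φ'' must be positive at stable fixed points")
    sds = tuple(1.0 / math.sqrt(omega * p2) for p2 in phi2)
    weights = (N * heights[0], N * heights[1])
    return GaussianPeakModel(centers=tuple(stable), sds=sds, weights=weights,
                             omega=omega)


def escape_rate_ratio(pot: WKBPotential, omega: float) -> float:
    """Kramers-type ratio of switching rates r_{low->high} / r_{high->low}.

    ratio = sqrt(Φ''(x1)/Φ''(x2)) · [N(x2)/N(x1)] · exp(+Ω[Φ(x1) - Φ(x2)])

    with x1 (x2) the low (high) stable state.  The orientation of the
    exponent is fixed so that the deeper potential well (smaller Φ) is
    the harder one to escape, as validated against exact mean
    first-passage times of the chain.  In "constant" prefactor mode the
    N ratio is dropped (the bare curvature-exponential estimate); the
    default "birth-death-standard" mode keeps it, which is what the
    stationary flux balance weight_1·r12 = weight_2·r21 requires and is
    markedly more accurate at moderate Ω.
    """
    fps = pot.fixed_points
    stable_idx = [i for i, s in enumerate(fps.stability) if s == "stable"]
    if len(stable_idx) != 2:
        raise ValueError("escape rate ratio requires bistable parameters")
    i1, i2 = stable_idx
    phi1, phi2c = pot.phi_at_fp[i1], pot.phi_at_fp[i2]
    c1, c2 = pot.phi2_at_fp[i1], pot.phi2_at_fp[i2]
    ratio = math.sqrt(c1 / c2) * math.exp(omega * (phi1 - phi2c))
    if pot.prefactor_mode == "birth-death-standard":
        x1, x2 = fps.roots[i1], fps.roots[i2]
        b1, d1 = _birth_death_conc(x1, pot.params)
        b2, d2 = _birth_death_conc(x2, pot.params)
        ratio *= math.sqrt((b1 * d1) / (b2 * d2))
    return float(ratio)
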