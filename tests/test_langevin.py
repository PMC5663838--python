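"""Flux-constrained Langevin paths, the action and trajectory entropy."""

import dataclasses
import math

import numpy as np
import pytest

from schloegl import (
    SchloeglParams,
    ensemble_entropy_production,
    langevin_entropy_production,
    path_action,
    path_entropy_production,
    simulate_langevin,
    steady_state_setup,
    weight_terms,
)


@pytest.fixture(scope="module")
def high_path(params):
    return simulate_langevin(params, "high", dt=1e-3, t_max=60.0, seed=3,
                             n_paths=60)


def test_setup_pins_flux_to_target_state(params):
    su = steady_state_setup(params, "high")
    x = su["x_star"]
    assert su["F"] == pytest.approx(0.5 - 3 * x, rel=1e-12)
    assert su["g_x"] == su["g_a"] + su["g_b"]
    su0 = steady_state_setup(params.with_(b_conc=1 / 6), "low")
    assert su0["F"] == pytest.approx(0.0, abs=1e-12)


def test_noiseless_limit_stays_at_fixed_point(params):
    path = simulate_langevin(params, "high", eps=0.0, dt=1e-3, t_max=5.0,
                             seed=0, n_paths=1)
    assert abs(path.x[0, -1] - steady_state_setup(params, "high")["x_star"]) \
        < 1e-4


def test_total_concentration_conserved(high_path):
    total = high_path.x + high_path.a + high_path.b
    assert np.abs(total - total[:, :1]).max() < 1e-10


def test_noise_anticorrelation(high_path):
    """Cov of x-increments with (a+b)-increments equals -ε g_x dt."""
    dx = np.diff(high_path.x, axis=1).ravel()
    dab = np.diff(high_path.a + high_path.b, axis=1).ravel()
    cov = np.cov(dx, dab)[0, 1]
    expected = -high_path.eps * high_path.g_x * high_path.dt
    n = len(dx)
    se = abs(expected) * math.sqrt(2.0 / n) * 3  # crude 3-sigma band
    assert abs(cov - expected) < max(se, 0.05 * abs(expected))


def test_stationary_mean_near_fixed_point(high_path, params):
    x_star = steady_state_setup(params, "high")["x_star"]
    xs = high_path.x[:, 20000:]
    assert abs(xs.mean() / x_star - 1) < 0.02


def test_equilibrium_mean_matches_x0():
    p = SchloeglParams(b_conc=1 / 6)
    path = simulate_langevin(p, "low", dt=2e-3, t_max=200.0, seed=5,
                             n_paths=30)
    xs = path.x[:, 50000:]
    per_path = xs.mean(axis=1)
    se = per_path.std(ddof=1) / math.sqrt(len(per_path))
    assert abs(per_path.mean() - 1 / 6) < 3 * se + 1e-4


class TestAction:
    def test_breakdown_sums_to_total(self, high_path, params):
        ab = path_action(high_path, params, path_index=0)
        assert ab.total == pytest.approx(
            ab.kinetic_potential + ab.entropy_production + ab.noise,
            rel=1e-12)

    def test_deterministic_path_has_zero_quadratic_term(self, params):
        path = simulate_langevin(params, "high", eps=0.0, dt=1e-3, t_max=2.0,
                                 seed=0, n_paths=1)
        ab = path_action(path, params)
        assert abs(ab.kinetic_potential) < 1e-18

    def test_time_reversal_antisymmetry(self, high_path, params):
        """A(-Γ) - A(Γ) equals minus twice the velocity-odd action part."""
        ab = path_action(high_path, params, path_index=0)
        rev = dataclasses.replace(
            high_path,
            x=high_path.x[:, ::-1].copy(),
            a=high_path.a[:, ::-1].copy(),
            b=high_path.b[:, ::-1].copy(),
        )
        ab_rev = path_action(rev, params, path_index=0)
        assert ab_rev.total - ab.total == pytest.approx(
            -2 * ab.entropy_production, rel=1e-9)

    def test_flux_velocity_cross_term_averages_out(self, high_path, params):
        """∫ F σ_q q̇ dt is a boundary term: small on stationary paths."""
        abs_diff = []
        for i in range(10):
            ab = path_action(high_path, params, path_index=i)
            abs_diff.append(ab.entropy_production - ab.ep_pure)
        # per-path bound: F·(q_T - q_0)/g* stays O(1) while the action
        # itself is extensive in time
        assert np.abs(abs_diff).max() < 0.05 * abs(
            path_action(high_path, params, 0).total)


class TestTrajectoryEntropy:
    def test_driven_high_state_produces_entropy(self, high_path, params):
        mean, se = ensemble_entropy_production(high_path, params,
                                              burn_in=20.0)
        assert mean > 3 * se

    def test_streaming_kernel_agrees_with_path_based(self, params):
        """Two independent estimators of the same ensemble mean."""
        path = simulate_langevin(params, "high", dt=1e-3, t_max=40.0,
                                 seed=21, n_paths=60)
        m1, se1 = ensemble_entropy_production(path, params, burn_in=10.0)
        dS = langevin_entropy_production(params, "high", dt=1e-3, t_max=40.0,
                                         burn_in=10.0, seed=22, n_paths=60)
        m2, se2 = dS.mean(), dS.std(ddof=1) / math.sqrt(len(dS))
        assert abs(m1 - m2) < 3 * math.hypot(se1, se2)

    def test_equilibrium_distribution_symmetric(self):
        """At (F=0, b0) the ΔS_Γ ensemble is symmetric about zero."""
        p = SchloeglParams(b_conc=1 / 6, omega=10000.0)
        dS = langevin_entropy_production(p, "low", dt=1e-3, t_max=120.0,
                                         burn_in=40.0, seed=4, n_paths=100)
        n = len(dS)
        mean, se = dS.mean(), dS.std(ddof=1) / math.sqrt(n)
        assert abs(mean) < 3 * se
        # bootstrap CI on the skewness contains 0
        rng = np.random.default_rng(0)
        idx = rng.integers(0, n, size=(1000, n))
        samples = dS[idx]
        sk = ((samples - samples.mean(axis=1, keepdims=True)) ** 3).mean(
            axis=1) / samples.std(axis=1) ** 3
        lo, hi = np.quantile(sk, [0.0015, 0.9985])
        assert lo <= 0.0 <= hi

    def test_burn_in_validation(self, high_path, params):
        with pytest.raises(ValueError):
            path_entropy_production(high_path, params, burn_in=1e4)


@pytest.fixture(scope="module")
def clamped_paths(params):
    return {
        st: simulate_langevin(params, st, eps=1e-3, dt=1e-3, t_max=40.0,
                              seed=31 + i, n_paths=40,
                              clamp_reservoirs=True)
        for i, st in enumerate(("low", "high"))
    }


class TestWeightTerms:

    def test_high_state_has_larger_ep_term(self, clamped_paths, params):
        wt = weight_terms(clamped_paths, params, burn_in=10.0)
        assert wt["high"]["schnakenberg_rate"] > wt["low"]["schnakenberg_rate"]
        assert wt["low"]["max_ep_state"] == "high"

    def test_schnakenberg_term_matches_macroscopic(self, clamped_paths,
                                                   params):
        """Small-noise limit: the per-state EP term is ½ the Eq.-16 rate."""
        from schloegl import find_fixed_points, macroscopic_entropy_production

        wt = weight_terms(clamped_paths, params, burn_in=10.0)
        lo, hi = find_fixed_points(params).stable_roots
        for name, x_star in (("low", lo), ("high", hi)):
            ref = macroscopic_entropy_production(x_star, params)[0] / 2
            assert abs(wt[name]["schnakenberg_rate"] / ref - 1) < 0.05

    def test_equilibrium_ep_terms_vanish(self):
        p = SchloeglParams(b_conc=1 / 6)
        path = simulate_langevin(p, "low", eps=1e-3, dt=1e-3, t_max=40.0,
                                 seed=41, n_paths=40, clamp_reservoirs=True)
        wt = weight_terms({"eq": path}, p, burn_in=10.0)
        # EP rate at b0 is ~O(eps) around exactly 0 at the fixed point
        assert abs(wt["eq"]["schnakenberg_rate"]) < 0.01

    def test_mixed_ensemble_rejected(self, params):
        """Unclamped low-state paths at b=4 escape: must be refused."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = simulate_langevin(params, "low", dt=1e-3, t_max=60.0,
                                     seed=51, n_paths=30)
        with pytest.raises(ValueError):
            weight_terms({"low": path}, params, burn_in=10.0)
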