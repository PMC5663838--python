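"""Master-equation solver: stationary pmf, entropy rates, partition, MFPT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg
from scipy.stats import poisson

from schloegl import (
    SchloeglParams,
    critical_b,
    entropy_rates,
    evolve_distribution,
    exact_mfpt,
    find_fixed_points,
    micro_propensities,
    partition_states,
    shannon_entropy,
    state_ep_delta_approx,
    stationary_distribution,
)
from schloegl.cme import generator_matrix, per_state_ep_contributions


class TestPropensities:
    def test_small_x_factors_vanish(self, params_o10):
        w = micro_propensities(2, params_o10)
        assert w[2] == 0.0  # X(X-1)(X-2) kills the triple annihilation
        w0 = micro_propensities(0, params_o10)
        assert w0[1] == w0[2] == w0[3] == 0.0 and w0[0] > 0  # reflecting at 0

    def test_arithmetic_at_X5(self, params_o10):
        # direct arithmetic: W+1 = 0.5*10, W-1 = 3*5, W+2 = 5*4*3/100,
        # W-2 = 4*5*4/10
        assert micro_propensities(5, params_o10) == pytest.approx(
            (5.0, 15.0, 0.6, 8.0))

    def test_macroscopic_limit(self):
        """W(X=Ωx)/Ω converges to the concentration rate laws."""
        from schloegl import macroscopic_rates

        x = 2.0
        p1000 = SchloeglParams(omega=1000.0)
        w = np.array(micro_propensities(2000, p1000)) / 1000.0
        ref = macroscopic_rates(x, p1000)
        assert w == pytest.approx(
            (ref.w_plus1, ref.w_minus1, ref.w_plus2, ref.w_minus2), rel=5e-3)

    def test_negative_X_rejected(self, params_o10):
        with pytest.raises(ValueError):
            micro_propensities(-1, params_o10)


class TestStationary:
    def test_linear_channel_is_poisson(self):
        """With channel 2 off, the chain is M/M/inf: Poisson(Ω k+1 a / k-1)."""
        p = SchloeglParams(k_plus2=0.0, k_minus2=0.0, omega=50.0)
        P = stationary_distribution(p, x_max=120)
        ref = poisson.pmf(P.support, 50 * 0.5 / 3.0)
        assert np.abs(P.pmf - ref).max() < 1e-12

    def test_detailed_balance_point_is_poisson(self):
        """At b0 every channel balances and the pmf is exactly Poisson."""
        p = SchloeglParams(b_conc=1 / 6, omega=60.0)
        P = stationary_distribution(p)
        ref = poisson.pmf(P.support, 60 / 6)
        assert np.abs(P.pmf - ref).max() < 1e-12

    def test_bimodal_modes_match_recursion_crossings(self, params):
        """Modes sit where the birth/death recursion ratio crosses one,
        within O(1/Ω) of the ODE roots 0.237·Ω and 3.078·Ω."""
        from schloegl.cme import propensity_arrays

        P = stationary_distribution(params)
        pmf = P.pmf
        interior = [i for i in range(1, len(pmf) - 1)
                    if pmf[i] > pmf[i - 1] and pmf[i] >= pmf[i + 1]]
        modes = sorted(sorted(interior, key=lambda i: -pmf[i])[:2])
        w_p1, w_m1, w_p2, w_m2 = propensity_arrays(P.x_max, params)
        ratio = (w_p1 + w_m2)[:-1] / (w_m1 + w_p2)[1:]
        down = np.flatnonzero((ratio[:-1] > 1) & (ratio[1:] <= 1))
        assert abs(modes[0] - (down[0] + 1)) <= 1
        assert abs(modes[1] - (down[1] + 1)) <= 1
        assert abs(modes[0] / 100.0 - 0.237) < 0.04
        assert abs(modes[1] / 100.0 - 3.078) < 0.04

    def test_matches_generator_null_space(self, params_o10, stat_o10):
        """Dense null-space oracle on the same truncation."""
        Q = generator_matrix(params_o10, stat_o10.x_max).toarray()
        ns = linalg.null_space(Q)
        assert ns.shape[1] == 1
        pi = ns[:, 0] / ns[:, 0].sum()
        assert np.abs(pi - stat_o10.pmf).max() < 1e-10

    def test_normalization_and_tail(self, stat_b365):
        assert stat_b365.pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (stat_b365.pmf >= 0).all()
        assert stat_b365.tail_mass_bound < 1e-10

    def test_stationarity_residual(self, params, stat_o10, params_o10):
        Q = generator_matrix(params_o10, stat_o10.x_max)
        assert np.abs(Q @ stat_o10.pmf).max() < 1e-10


class TestEntropyRates:
    def test_zero_at_detailed_balance(self):
        p = SchloeglParams(b_conc=1 / 6, omega=30.0)
        P = stationary_distribution(p)
        dsi, dse = entropy_rates(P.pmf, p)
        assert abs(dsi) < 1e-10
        assert abs(dse) < 1e-10

    def test_production_balances_flow_at_stationarity(self, params_o10,
                                                      stat_o10):
        dsi, dse = entropy_rates(stat_o10.pmf, params_o10)
        assert dsi > 0
        assert dsi == pytest.approx(-dse, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_second_law_for_arbitrary_distributions(self, seed):
        """dS_i/dt >= 0 for any pmf, not only the stationary one."""
        rng = np.random.default_rng(seed)
        p = SchloeglParams(omega=10.0, b_conc=float(rng.uniform(0.2, 5.0)))
        pmf = rng.dirichlet(np.ones(80) * rng.uniform(0.2, 2.0))
        dsi, _ = entropy_rates(pmf, p)
        assert dsi >= -1e-12

    def test_extensivity_of_stationary_rate(self):
        """dS_i/dt / Ω converges as the volume doubles (away from b_c)."""
        rates = []
        for om in (25.0, 50.0, 100.0):
            p = SchloeglParams(b_conc=5.0, omega=om)
            dsi, _ = entropy_rates(stationary_distribution(p).pmf, p)
            rates.append(dsi / om)
        assert abs(rates[1] / rates[0] - 1) < 0.02
        assert abs(rates[2] / rates[1] - 1) < 0.02

    def test_per_state_contributions_sum_to_total(self, params_o10, stat_o10):
        contrib = per_state_ep_contributions(stat_o10.pmf, params_o10)
        dsi, _ = entropy_rates(stat_o10.pmf, params_o10)
        assert contrib.sum() == pytest.approx(dsi, rel=1e-9)


class TestTransient:
    @staticmethod
    def _trimmed(stat, n=90):
        p = stat.pmf[:n].copy()
        return p / p.sum()

    def test_stationary_start_is_invariant(self, params_o10, stat_o10):
        t_grid = [0.0, 0.5, 2.0]
        sol = evolve_distribution(self._trimmed(stat_o10), t_grid, params_o10)
        assert np.ptp(sol.entropy) < 1e-8
        assert sol.dsi_dt == pytest.approx(-sol.dse_dt, rel=1e-6)

    def test_relaxation_from_delta(self, params_o10, stat_o10):
        P0 = np.zeros(90)
        P0[0] = 1.0
        sol = evolve_distribution(P0, [0.1, 1.0, 5.0, 400.0], params_o10)
        assert (sol.dsi_dt >= -1e-12).all()
        tv = 0.5 * np.abs(sol.pmf_t[-1] - self._trimmed(stat_o10)).sum()
        assert tv < 1e-6
        # pmfs stay normalized
        assert np.allclose(sol.pmf_t.sum(axis=1), 1.0, atol=1e-9)

    def test_entropy_balance_identity(self, params_o10, stat_o10):
        """dS/dt = dS_i/dt + dS_e/dt along the transient (finite differences)."""
        P0 = np.zeros(90)
        P0[0] = 1.0
        h = 1e-4
        for t in (0.2, 0.5, 1.0, 2.0):
            sol = evolve_distribution(P0, [t - h, t, t + h], params_o10)
            dS_dt = (sol.entropy[2] - sol.entropy[0]) / (2 * h)
            resid = abs(dS_dt - (sol.dsi_dt[1] + sol.dse_dt[1]))
            assert resid < 1e-6

    def test_bdf_cross_check(self, params_o10, stat_o10):
        P0 = np.zeros(90)
        P0[0] = 1.0
        t_grid = [0.5, 2.0]
        a = evolve_distribution(P0, t_grid, params_o10, method="expm")
        b = evolve_distribution(P0, t_grid, params_o10, method="bdf")
        assert np.abs(a.pmf_t - b.pmf_t).max() < 1e-6

    def test_rejects_unnormalized_input(self, params_o10, stat_o10):
        with pytest.raises(ValueError):
            evolve_distribution(self._trimmed(stat_o10) * 2, [1.0],
                                params_o10)


class TestPartition:
    def test_separatrix_near_critical_driving(self, params_b365, stat_b365):
        part = partition_states(stat_b365, params_b365)
        assert part.bimodal
        assert 0.85 <= part.separatrix_x <= 0.95
        assert sum(part.weights) == pytest.approx(1.0, abs=1e-12)
        assert sum(part.ep_rates) == pytest.approx(
            entropy_rates(stat_b365.pmf, params_b365)[0], rel=1e-9)
        assert all(r >= 0 for r in part.ep_rates)

    def test_monostable_returns_single_state(self):
        p = SchloeglParams(b_conc=1.0)
        P = stationary_distribution(p)
        part = partition_states(P, p)
        assert not part.bimodal
        assert part.weights == (1.0,)
        assert part.ep_rates[0] == pytest.approx(
            entropy_rates(P.pmf, p)[0], rel=1e-9)

    def test_weight_and_ep_order_agree_across_crossing(self, params):
        for b in (3.45, 3.5, 3.7, 3.9):
            p = params.with_(b_conc=b)
            part = partition_states(stationary_distribution(p), p)
            assert part.bimodal
            assert np.sign(part.weights[1] - part.weights[0]) == np.sign(
                part.ep_rates[1] - part.ep_rates[0])


class TestDeltaApprox:
    def test_matches_partition_ordering(self, params_b365, stat_b365):
        fps = find_fixed_points(params_b365)
        ep = state_ep_delta_approx(params_b365, stat_b365, fps)
        part = partition_states(stat_b365, params_b365)
        assert np.sign(ep[1] - ep[0]) == np.sign(
            part.ep_rates[1] - part.ep_rates[0])

    def test_high_state_dominates_at_b4(self, params):
        P = stationary_distribution(params)
        ep = state_ep_delta_approx(params, P, find_fixed_points(params))
        assert ep[1] > ep[0]

    def test_equal_heights_reduce_to_macroscopic_ratio(self, params_b365,
                                                       stat_b365):
        """With N·p canceling, the EP ratio is the ratio of Eq.-16 rates."""
        from schloegl import macroscopic_entropy_production

        fps = find_fixed_points(params_b365)
        ep = state_ep_delta_approx(params_b365, stat_b365, fps)
        x1, x2 = fps.stable_roots
        ds1 = macroscopic_entropy_production(x1, params_b365)[0]
        ds2 = macroscopic_entropy_production(x2, params_b365)[0]
        heights = np.array(ep) / np.array([ds1, ds2])
        # heights are the normalized peak weights: ratio matches the pmf
        assert heights[0] > 0 and heights[1] > 0

    def test_monostable_rejected(self):
        p = SchloeglParams(b_conc=1.0)
        P = stationary_distribution(p)
        with pytest.raises(ValueError):
            state_ep_delta_approx(p, P, find_fixed_points(p))


class TestCriticalB:
    def test_weight_crossing_location(self, params):
        crit = critical_b(params)
        assert abs(crit["b_weight"] - 3.65) <= 0.1

    def test_ep_crossing_close_to_weight_crossing(self, params):
        crit = critical_b(params)
        assert abs(crit["b_weight"] - crit["b_ep"]) < 0.15

    def test_bad_bracket_raises(self, params):
        with pytest.raises(ValueError):
            critical_b(params, bracket=(0.5, 1.0))


class TestMFPT:
    def test_pure_birth_single_step(self):
        p = SchloeglParams(k_minus1=1e-12, k_plus2=0.0, k_minus2=0.0,
                           omega=10.0)
        # birth rate k+1 a Ω = 5; MFPT(X -> X+1) = 1/5
        assert exact_mfpt(p, 3, 4, x_max=200) == pytest.approx(0.2, rel=1e-6)

    def test_agrees_with_dense_linear_solve(self, params_o10, stat_o10):
        """First-passage system (Q restricted) solved densely as oracle."""
        target = 25
        m = stat_o10.x_max
        Q = generator_matrix(params_o10, m).toarray()
        QT = Q.T  # dP/dt = QP => mean hitting times solve Q^T tau = -1
        keep = [i for i in range(m + 1) if i != target]
        A = QT[np.ix_(keep, keep)]
        tau = np.linalg.solve(A, -np.ones(len(keep)))
        for start in (2, 10, 60):
            idx = keep.index(start)
            assert exact_mfpt(params_o10, start, target) == pytest.approx(
                tau[idx], rel=1e-8)

    def test_switching_asymmetry_matches_weights(self, params_b365):
        """Passage into the dominant state is faster than out of it."""
        p = params_b365.with_(omega=30.0)
        lo, hi = 7, 92
        m12 = exact_mfpt(p, lo, hi)
        m21 = exact_mfpt(p, hi, lo)
        P = stationary_distribution(p)
        part = partition_states(P, p)
        dominant_high = part.weights[1] > part.weights[0]
        assert (m12 < m21) == dominant_high

    def test_same_state_rejected(self, params_o10):
        with pytest.raises(ValueError):
            exact_mfpt(params_o10, 5, 5)


def test_shannon_entropy_of_uniform():
    assert shannon_entropy(np.full(8, 1 / 8)) == pytest.approx(np.log(8))
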