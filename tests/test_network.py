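import dataclasses

import numpy as np
import pytest

from alnbrain.network import (Connectome, GlobalParams, NodeState,
                              PopulationParams, effective_input_rates,
                              node_step, ou_step, simulate)


class TestOUProcess:
    def test_noiseless_zero_is_fixed_point(self):
        rng = np.random.default_rng(0)
        x = 0.0
        for _ in range(100):
            x = ou_step(x, 0.0, 5.0, 0.1, rng)
        assert x == 0.0

    def test_noiseless_exponential_relaxation(self):
        rng = np.random.default_rng(0)
        dt, tau = 0.01, 5.0
        x = np.array(1.0)
        n = 1000  # 10 ms
        for _ in range(n):
            x = ou_step(x, 0.0, tau, dt, rng)
        expected = np.exp(-n * dt / tau)
        assert x == pytest.approx(expected, rel=5e-3)  # Euler error only

    def test_stationary_variance_closed_form(self):
        sigma_ou, tau_ou, dt = 0.19, 5.0, 0.1
        rng = np.random.default_rng(42)
        x = np.zeros(500)
        burn, keep = 2000, 2000
        samples = []
        for t in range(burn + keep):
            x = ou_step(x, sigma_ou, tau_ou, dt, rng)
            if t >= burn:
                samples.append(x.copy())
        var = np.concatenate(samples).var()
        expected = sigma_ou ** 2 * tau_ou / 2.0
        assert var == pytest.approx(expected, rel=0.05)


class TestEffectiveInputRates:
    def test_uncoupled_reduction_exact(self):
        pop = PopulationParams()
        con = Connectome(C=np.zeros((1, 1)), D=np.zeros((1, 1)))
        rate = 0.013
        T = 200
        hist = {"r_E": np.full((1, T), rate), "r_I": np.zeros((1, T))}
        r_ab, rho_ab = effective_input_rates(hist, con, pop, K_gl=0.0)
        expected = pop.c_EE / pop.J_EE * pop.tau_s_E * pop.K_E * rate
        assert r_ab["EE"][0] == pytest.approx(expected, rel=1e-12)
        assert r_ab["EI"][0] == 0.0

    def test_single_edge_delayed_propagation(self):
        pop = PopulationParams()
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        con = Connectome(C=np.array([[0.0, 1.0], [1.0, 0.0]]), D=D)
        T = 100
        rE = np.zeros((2, T))
        peak_rate = 0.02
        d_steps = 30  # 3 ms at dt=0.1
        rE[1, T - 1 - d_steps] = peak_rate  # only node 2 fired, D_12 ago
        hist = {"r_E": rE, "r_I": np.zeros((2, T))}
        r_ab, _ = effective_input_rates(hist, con, pop, K_gl=7.0)
        pref = pop.c_EE / pop.J_EE * pop.tau_s_E
        assert r_ab["EE"][0] == pytest.approx(pref * 7.0 * peak_rate, rel=1e-12)

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        n, T = 5, 120
        pop = PopulationParams()
        C = rng.random((n, n))
        np.fill_diagonal(C, 0)
        C = (C + C.T) / 2
        C /= C.max()
        D = rng.integers(0, 8, (n, n)).astype(float)
        D = (D + D.T) / 2
        con = Connectome(C=C, D=D)
        rE = rng.random((n, T)) * 0.05
        rI = rng.random((n, T)) * 0.05
        K_gl = 100.0
        r_ab, rho_ab = effective_input_rates({"r_E": rE, "r_I": rI}, con, pop,
                                             K_gl, dt=0.1)
        # independent evaluation of the printed sums
        dE = int(round(pop.d_E / 0.1))
        for i in range(n):
            inter = sum(C[i, j] * rE[j, T - 1 - int(round(D[i, j] / 0.1))]
                        for j in range(n))
            inter2 = sum(C[i, j] ** 2 * rE[j, T - 1 - int(round(D[i, j] / 0.1))]
                         for j in range(n))
            pref = pop.c_EE / pop.J_EE * pop.tau_s_E
            want = pref * (pop.K_E * rE[i, T - 1 - dE] + K_gl * inter)
            want_rho = pref ** 2 * (pop.K_E * rE[i, T - 1 - dE] + K_gl * inter2)
            assert r_ab["EE"][i] == pytest.approx(want, rel=1e-12)
            assert rho_ab["EE"][i] == pytest.approx(want_rho, rel=1e-12)

    def test_buffer_underrun_names_required_depth(self):
        pop = PopulationParams()
        con = Connectome(C=np.zeros((1, 1)), D=np.zeros((1, 1)))
        hist = {"r_E": np.zeros((1, 10)), "r_I": np.zeros((1, 10))}
        with pytest.raises(ValueError, match="41"):
            effective_input_rates(hist, con, pop, K_gl=0.0)


class TestNodeStep:
    def test_silent_down_state_is_fixed_point(self, tables_small):
        pop = PopulationParams(mu_E_ext=0.0, mu_I_ext=0.0, sigma_ext=0.25)
        state = NodeState.zeros(1)
        zero = {k: np.zeros(1) for k in ("EE", "EI", "IE", "II")}
        for _ in range(300):
            state, clamps = node_step(state, zero, zero, tables_small, pop, 0.1)
        assert state.r_E[0] < 1e-5
        assert abs(state.mu_E[0]) < 1e-6
        assert state.s_EE[0] == 0.0

    def test_adaptation_decays_without_inflow(self, tables_small):
        pop = PopulationParams(alpha=0.0, beta=0.0, mu_E_ext=0.0,
                               mu_I_ext=0.0, sigma_ext=0.25)
        state = NodeState.zeros(1)
        state.I_A = np.array([150.0])
        zero = {k: np.zeros(1) for k in ("EE", "EI", "IE", "II")}
        n = 1000  # 100 ms, tau_A = 200 ms
        for _ in range(n):
            state, _ = node_step(state, zero, zero, tables_small, pop, 0.1)
        assert state.I_A[0] == pytest.approx(150.0 * np.exp(-0.5), rel=0.01)

    def test_synapse_bounds_hold_under_extreme_drive(self, tables_small):
        pop = PopulationParams()
        state = NodeState.zeros(1)
        huge = {k: np.full(1, 500.0) for k in ("EE", "EI", "IE", "II")}
        rho = {k: np.full(1, 50.0) for k in ("EE", "EI", "IE", "II")}
        total_clamps = 0
        for _ in range(200):
            state, clamps = node_step(state, huge, rho, tables_small, pop, 0.1)
            total_clamps += clamps
        for key in ("EE", "EI", "IE", "II"):
            assert 0.0 <= getattr(state, f"s_{key}")[0] <= 1.0
            assert getattr(state, f"v_{key}")[0] >= 0.0
        assert total_clamps == 0


class TestSimulate:
    def test_same_seed_bit_identical(self, connectome16, tables_small,
                                     short_glob):
        pop = PopulationParams()
        a = simulate(connectome16, pop, short_glob, 3, tables_small)
        b = simulate(connectome16, pop, short_glob, 3, tables_small)
        assert np.array_equal(a.rate_E, b.rate_E)

    def test_different_seed_differs(self, connectome16, tables_small,
                                    short_glob):
        pop = PopulationParams()
        a = simulate(connectome16, pop, short_glob, 3, tables_small)
        b = simulate(connectome16, pop, short_glob, 4, tables_small)
        assert not np.array_equal(a.rate_E, b.rate_E)

    def test_disconnected_identical_nodes_same_streams(self, tables_small):
        con = Connectome(C=np.zeros((2, 2)), D=np.zeros((2, 2)))
        pop = PopulationParams(mu_E_ext=3.0)
        glob = GlobalParams(duration=3.0, transient=0.5)
        n_steps = int(round(glob.duration * 1000 / glob.dt))
        rng = np.random.default_rng(9)
        base = rng.standard_normal((n_steps, 2))
        noise = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 1]])
        out = simulate(con, pop, glob, 0, tables_small, noise=noise)
        np.testing.assert_array_equal(out.rate_E[0], out.rate_E[1])

    def test_zero_coupling_decouples_network(self, tables_small):
        """K_gl=0 network statistics equal single-node runs with same streams."""
        pop = PopulationParams(mu_E_ext=3.0)
        glob = GlobalParams(duration=3.0, transient=0.5, K_gl=0.0)
        n_steps = int(round(glob.duration * 1000 / glob.dt))
        rng = np.random.default_rng(10)
        noise2 = rng.standard_normal((n_steps, 4))
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        con2 = Connectome(C=C, D=np.ones((2, 2)) - np.eye(2))
        out2 = simulate(con2, pop, glob, 0, tables_small, noise=noise2)
        con1 = Connectome(C=np.zeros((1, 1)), D=np.zeros((1, 1)))
        for node in range(2):
            noise1 = noise2[:, [node, 2 + node]]
            out1 = simulate(con1, pop, glob, 0, tables_small, noise=noise1)
            np.testing.assert_allclose(out1.rate_E[0], out2.rate_E[node],
                                       atol=1e-14)

    def test_rates_bounded_and_finite_no_clamps(self, connectome16,
                                                tables_small):
        pop = PopulationParams()
        glob = GlobalParams(duration=10.0, transient=2.0)
        out = simulate(connectome16, pop, glob, 1, tables_small)
        assert np.all(np.isfinite(out.rate_E))
        assert out.rate_E.min() >= 0.0
        assert out.rate_E.max() <= 0.2  # kHz
        assert out.n_clamp_events == 0

    def test_output_shape_matches_contract(self, connectome16, tables_small,
                                           short_glob):
        out = simulate(connectome16, PopulationParams(), short_glob, 0,
                       tables_small)
        expected_T = int((short_glob.duration - short_glob.transient) * 1000
                         / out.output_step_ms)
        assert out.rate_E.shape == (connectome16.n, expected_T)

    def test_halving_dt_converges(self, tables_small, single_node):
        """Euler convergence: mean stationary rate shifts <2% when dt halves."""
        pop = PopulationParams(mu_E_ext=5.5)
        means = []
        for dt in (0.1, 0.05):
            glob = GlobalParams(duration=6.0, transient=3.0, sigma_ou=0.0,
                                dt=dt)
            out = simulate(single_node, pop, glob, 0, tables_small)
            means.append(out.rate_E.mean())
        assert abs(means[0] - means[1]) / means[1] < 0.02
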