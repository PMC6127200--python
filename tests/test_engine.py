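import math
import time

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qacolink import (
    AntPath,
    QACOError,
    QACOParams,
    compute_visibility,
    init_pheromone,
    init_register,
    path_fitness,
    quantum_intensity,
    rotate_qubit,
    run_qaco,
    transition_distribution,
    update_pheromone,
    update_register,
    walk_ant,
)
from qacolink.engine import ALPHA_SQ_FLOOR
from conftest import build_graph, random_connected_graph, visibility_oracle

S2 = 1.0 / math.sqrt(2.0)


class TestInitPheromone:
    def test_uniform_offdiagonal(self):
        tau = init_pheromone(3, 1.0)
        off = tau[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)

    def test_value_and_symmetry(self):
        tau = init_pheromone(2, 0.5)
        assert tau[0, 1] == tau[1, 0] == 0.5
        assert np.all(np.diag(tau) == 0.0)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(QACOError):
            init_pheromone(3, 0.0)


class TestVisibility:
    def test_path3_values(self, path3):
        eta = compute_visibility(path3, iota=1, omega=0.01)
        a, b, c = (path3.index_of(x) for x in "abc")
        assert eta[a, c] == pytest.approx(0.5)  # common neighbour b, k(b)=2
        assert eta[a, b] == 0.0

    def test_path4_length3_term(self, path4):
        eta = compute_visibility(path4, iota=1, omega=0.01)
        a, d = path4.index_of("a"), path4.index_of("d")
        # single 3-path a-b-c-d with k(b)=k(c)=2
        assert eta[a, d] == pytest.approx(0.01 * 0.25)

    def test_cycle4_common_neighbours(self, cycle4):
        eta = compute_visibility(cycle4, iota=1, omega=0.01)
        a, c = cycle4.index_of("a"), cycle4.index_of("c")
        assert eta[a, c] == pytest.approx(1.0)  # b and d, degree 2 each

    @pytest.mark.parametrize("iota", [0, 1])
    def test_matches_oracle_on_random_graphs(self, iota):
        rng = np.random.default_rng(42)
        for _ in range(60):
            g = random_connected_graph(int(rng.integers(3, 8)), rng)
            got = compute_visibility(g, iota=iota, omega=0.01)
            want = visibility_oracle(g, iota=iota, omega=0.01)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_symmetric_zero_diagonal(self, cycle4):
        eta = compute_visibility(cycle4, iota=1, omega=0.01)
        np.testing.assert_allclose(eta, eta.T)
        assert np.all(np.diag(eta) == 0.0)

    def test_bad_iota_rejected(self, path3):
        with pytest.raises(QACOError):
            compute_visibility(path3, iota=2)


class TestQuantumRegister:
    def test_balanced_init(self):
        reg = init_register(2, 1)
        np.testing.assert_allclose(reg, S2, atol=1e-15)
        np.testing.assert_allclose((reg ** 2).sum(-1), 1.0, atol=1e-12)

    def test_initial_intensity_is_two(self):
        reg = init_register(4, 3)
        for j in range(4):
            for k in range(3):
                assert quantum_intensity(reg, j, k) == pytest.approx(2.0)

    def test_intensity_basis_states_and_floor(self):
        reg = np.zeros((2, 1, 2))
        reg[0, 0] = (1.0, 0.0)
        reg[1, 0] = (0.0, 1.0)
        assert quantum_intensity(reg, 0, 0) == pytest.approx(1.0)
        assert quantum_intensity(reg, 1, 0) == pytest.approx(1.0 / ALPHA_SQ_FLOOR)


class TestRotationGate:
    def test_balanced_state_quarter_turn(self):
        a, b = rotate_qubit(S2, S2, math.pi / 4)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_basis_state_is_fixed_point(self):
        for dt in (0.01 * math.pi, 0.05 * math.pi, 0.08 * math.pi):
            assert rotate_qubit(1.0, 0.0, dt) == (1.0, 0.0)

    def test_negative_product_rotates_toward_minus_one_state(self):
        # sign(α·β) = −1 ⇒ θ = −π/4, carrying the −45° state to −|1⟩
        a, b = rotate_qubit(S2, -S2, math.pi / 4)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(-1.0, abs=1e-12)

    @given(
        phi=st.floats(0.0, 2.0 * math.pi),
        dtheta=st.floats(0.01 * math.pi, 0.08 * math.pi),
    )
    @settings(max_examples=200, derandomize=True)
    def test_norm_preserved(self, phi, dtheta):
        a, b = rotate_qubit(math.cos(phi), math.sin(phi), dtheta)
        assert a * a + b * b == pytest.approx(1.0, abs=1e-12)


class TestTransition:
    def setup_method(self):
        self.p = QACOParams()

    def test_symmetric_triangle_is_uniform(self, triangle):
        tau = init_pheromone(3, 1.0)
        eta = compute_visibility(triangle, iota=1, omega=0.01)
        reg = init_register(3, 1)
        cand, probs = transition_distribution(0, set(), tau, eta, reg, 0, self.p)
        assert list(cand) == [1, 2]
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_pheromone_ratio(self):
        # two candidates, τ = (2, 1), η = μ = 1, λ = 1 → (2/3, 1/3)
        tau = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        eta = np.ones((3, 3))
        np.fill_diagonal(eta, 0.0)
        reg = np.zeros((3, 1, 2))
        reg[:, 0, 0] = 1.0  # α = 1 ⇒ μ = 1
        p = QACOParams(kappa=1.0)
        _, probs = transition_distribution(0, set(), tau, eta, reg, 0, p)
        np.testing.assert_allclose(probs, [2 / 3, 1 / 3])

    def test_all_zero_weights_fall_back_to_uniform(self):
        tau = init_pheromone(3, 1.0)
        eta = np.zeros((3, 3))  # κ = 2 ⇒ every weight 0
        reg = init_register(3, 1)
        _, probs = transition_distribution(0, set(), tau, eta, reg, 0, self.p)
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_empty_candidates_signal_termination(self):
        tau = init_pheromone(3, 1.0)
        eta = np.ones((3, 3))
        reg = init_register(3, 1)
        cand, probs = transition_distribution(0, {1, 2}, tau, eta, reg, 0, self.p)
        assert cand.size == 0 and probs.size == 0

    @given(seed=st.integers(0, 10 ** 6))
    @settings(max_examples=50, derandomize=True)
    def test_distribution_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(6, rng)
        tau = init_pheromone(6, 1.0) * rng.uniform(0.5, 2.0, (6, 6))
        tau = 0.5 * (tau + tau.T)
        np.fill_diagonal(tau, 0.0)
        eta = compute_visibility(g, iota=1, omega=0.01)
        reg = init_register(6, 2)
        cand, probs = transition_distribution(
            int(rng.integers(6)), set(), tau, eta, reg, 1, self.p
        )
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestWalk:
    def test_tabu_exhausts_two_node_graph(self):
        tau = init_pheromone(2, 1.0)
        eta = np.ones((2, 2))
        np.fill_diagonal(eta, 0.0)
        reg = init_register(2, 1)
        path = walk_ant(0, 5, tau, eta, reg, 0, QACOParams(), np.random.default_rng(0))
        assert len(path.nodes) == 2

    def test_no_repeats_and_determinism(self, cycle4):
        tau = init_pheromone(4, 1.0)
        eta = compute_visibility(cycle4, iota=1, omega=0.01)
        reg = init_register(4, 1)
        p = QACOParams()
        p1 = walk_ant(0, 4, tau, eta, reg, 0, p, np.random.default_rng(9))
        p2 = walk_ant(0, 4, tau, eta, reg, 0, p, np.random.default_rng(9))
        assert p1.nodes == p2.nodes
        assert len(set(p1.nodes)) == len(p1.nodes)

    def test_antpath_rejects_revisit(self):
        with pytest.raises(QACOError):
            AntPath(ant_index=0, nodes=(0, 1, 0))


class TestFitness:
    def test_triangle_mean_degree(self, triangle):
        path = AntPath(0, tuple(range(3)))
        assert path_fitness(path, triangle, C=1.0) == pytest.approx(2.0)

    def test_star_mean_degree(self):
        g = build_graph([("c", "l1"), ("c", "l2"), ("c", "l3")])
        path = AntPath(0, (g.index_of("c"), g.index_of("l1"), g.index_of("l2")))
        assert path_fitness(path, g, C=1.0) == pytest.approx(5 / 3)

    def test_zero_gain(self, triangle):
        path = AntPath(0, (0, 1))
        assert path_fitness(path, triangle, C=0.0) == 0.0


class TestPheromoneUpdate:
    def test_decay_only_when_not_traversed(self):
        tau = init_pheromone(3, 1.0)
        reg = init_register(3, 1)
        out = update_pheromone(tau, [AntPath(0, (1, 2))], [1.0], reg, rho=0.9)
        assert out[0, 1] == pytest.approx(0.9)  # pair (0,1) untouched

    def test_deposit_arithmetic(self):
        tau = init_pheromone(3, 1.0)
        reg = np.zeros((3, 1, 2))
        reg[:, 0, 0] = S2
        reg[:, 0, 1] = S2  # β² = 0.5 everywhere
        out = update_pheromone(tau, [AntPath(0, (0, 1))], [2.0], reg, rho=0.9)
        assert out[0, 1] == pytest.approx(0.9 + 2.0 * 0.5)
        assert out[1, 0] == out[0, 1]

    def test_no_ants_is_pure_decay(self):
        tau = init_pheromone(4, 2.0)
        reg = init_register(4, 1)
        out = update_pheromone(tau, [], [], reg, rho=0.9)
        np.testing.assert_allclose(out, 0.9 * tau)

    def test_mismatched_fitnesses_rejected(self):
        tau = init_pheromone(3, 1.0)
        reg = init_register(3, 1)
        with pytest.raises(QACOError):
            update_pheromone(tau, [AntPath(0, (0, 1))], [], reg, rho=0.9)

    def test_stays_symmetric_nonnegative(self):
        rng = np.random.default_rng(3)
        tau = init_pheromone(5, 1.0)
        reg = init_register(5, 2)
        paths = [AntPath(0, (0, 2, 4)), AntPath(1, (1, 3))]
        out = update_pheromone(tau, paths, [2.0, 3.0], reg, rho=0.9)
        np.testing.assert_allclose(out, out.T)
        assert np.all(out >= 0.0)
        assert np.all(np.diag(out) == 0.0)


class TestRegisterUpdate:
    def test_empty_paths_identity(self):
        reg = init_register(3, 2)
        np.testing.assert_array_equal(update_register(reg, [], 0.05 * math.pi), reg)

    def test_locality(self):
        reg = init_register(3, 2)
        out = update_register(reg, [AntPath(0, (1,))], 0.05 * math.pi)
        changed = np.any(out != reg, axis=2)
        assert changed[1, 0]
        assert changed.sum() == 1  # only node 1 / ant 0

    def test_visit_increases_attractiveness(self):
        reg = init_register(2, 1)
        out = update_register(reg, [AntPath(0, (0,))], 0.05 * math.pi)
        assert out[0, 0, 0] < reg[0, 0, 0]  # α shrinks
        assert out[0, 0, 1] > reg[0, 0, 1]  # β grows
        assert quantum_intensity(out, 0, 0) > quantum_intensity(reg, 0, 0)
        np.testing.assert_allclose((out ** 2).sum(-1), 1.0, atol=1e-12)


class TestRunQACO:
    def test_zero_iterations_is_delta_plus_eps_eta(self, cycle4):
        p = QACOParams(n_ants=2, n_iter=0, seed=5)
        s = run_qaco(cycle4, p)
        eta = compute_visibility(cycle4, iota=1, omega=0.01)
        np.testing.assert_allclose(
            s.values[~np.eye(4, dtype=bool)],
            (1.0 + 0.2 * eta)[~np.eye(4, dtype=bool)],
        )

    def test_fixed_seed_bitwise_identical(self):
        g = random_connected_graph(12, np.random.default_rng(1))
        p = QACOParams(n_ants=6, n_iter=5, seed=17)
        s1, s2 = run_qaco(g, p), run_qaco(g, p)
        assert np.array_equal(s1.values, s2.values)

    def test_unitarity_after_many_iterations(self):
        """The register norm survives a full run (checked via a rerun hook)."""
        g = random_connected_graph(10, np.random.default_rng(2))
        from qacolink import engine as eng

        p = QACOParams(n_ants=5, n_iter=30, seed=3)
        reg = eng.init_register(g.n_nodes, p.n_ants)
        tau = eng.init_pheromone(g.n_nodes, p.delta)
        eta = eng.compute_visibility(g, p.iota, p.omega)
        rng = np.random.default_rng(p.seed)
        for _ in range(p.n_iter):
            paths = [
                eng.walk_ant(int(rng.integers(g.n_nodes)), g.n_nodes, tau, eta, reg, k, p, rng)
                for k in range(p.n_ants)
            ]
            fits = [eng.path_fitness(path, g, p.C) for path in paths]
            tau = eng.update_pheromone(tau, paths, fits, reg, p.rho)
            reg = eng.update_register(reg, paths, p.dtheta)
        np.testing.assert_allclose((reg ** 2).sum(-1), 1.0, atol=1e-9)

    def test_too_many_ants_rejected(self, triangle):
        with pytest.raises(QACOError):
            run_qaco(triangle, QACOParams(n_ants=10))

    def test_quadratic_complexity_smoke(self):
        """Doubling-ish n should cost more wall time (loose monotonicity)."""
        from qacolink import WSParams, generate_ws

        def timed(n):
            g = generate_ws(WSParams(N=n, m_half=3, beta=0.1, seed=0))
            p = QACOParams(n_ants=10, n_iter=3, seed=0)
            t0 = time.perf_counter()
            run_qaco(g, p)
            return time.perf_counter() - t0

        timed(40)  # warm-up
        t_small = min(timed(40) for _ in range(2))
        t_big = min(timed(160) for _ in range(2))
        assert t_big > 1.5 * t_small
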