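"""Shocks, energy production, recruitment, exploration and full runs."""

import networkx as nx
import numpy as np
import pytest

from collapsim import (
    ModelParams,
    SocietyState,
    ValidationError,
    build_network,
    compute_energy,
    draw_shock,
    exploration_step,
    roc_curve,
    run_simulation,
    select_recruit,
    step,
)
from collapsim.dynamics import CAUSE_CENSORED, CAUSE_COLLAPSE, SimulationResult


def make_state(edges, n):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return SocietyState(g)


class TestDrawShock:
    def test_sample_mean_matches_beta_expectation(self, defaults, rng):
        # E[R] = R_max * (1 - alpha/(alpha+beta)) = R_max * 15/16
        draws = np.array([draw_shock(defaults, rng) for _ in range(100_000)])
        assert draws.min() >= 0.0 and draws.max() <= defaults.r_max
        expected = defaults.r_max * 15 / 16
        var_b = (1 * 15) / (16**2 * 17)
        se = defaults.r_max * np.sqrt(var_b / len(draws))
        assert abs(draws.mean() - expected) < 5 * se

    def test_tail_probability_matches_closed_form(self, defaults, rng):
        # for Beta(1, beta) the survival function is P(B > x) = (1-x)^beta
        draws = np.array([draw_shock(defaults, rng) for _ in range(100_000)])
        b = 1.0 - draws / defaults.r_max
        expected = 0.8**15  # = 0.035184372088832
        freq = (b > 0.2).mean()
        se = np.sqrt(expected * (1 - expected) / len(draws))
        assert abs(freq - expected) < 5 * se

    def test_large_beta_limit_removes_shocks(self, rng):
        p = ModelParams(beta=1e9)
        draws = [draw_shock(p, rng) for _ in range(100)]
        assert np.allclose(draws, p.r_max, rtol=1e-6)

    def test_invalid_shape_parameters_rejected(self):
        with pytest.raises(ValidationError):
            ModelParams(alpha=0.0)
        with pytest.raises(ValidationError):
            ModelParams(beta=0.0)


class TestComputeEnergy:
    def test_unperturbed_per_capita_energy_is_one(self, defaults):
        # the R_max = N^(1-a) scaling calibrates E/N to exactly 1
        e = compute_energy(400, 0, defaults.r_max, defaults)
        assert e / 400 == pytest.approx(1.0, abs=1e-12)

    def test_no_labor_no_energy(self, defaults):
        assert compute_energy(0, 0, 3.7, defaults) == 0.0

    def test_known_value(self):
        # 10**0.75 + 1.05 * 5**0.75, frozen from a 30-digit evaluation
        p = ModelParams(a=0.75, b=0.75, c=1.05)
        assert compute_energy(10, 5, 1.0, p) == pytest.approx(
            9.134299853029706, rel=1e-12
        )

    def test_negative_inputs_rejected(self, defaults):
        with pytest.raises(ValueError):
            compute_energy(-1, 0, 1.0, defaults)
        with pytest.raises(ValueError):
            compute_energy(0, -1, 1.0, defaults)
        with pytest.raises(ValueError):
            compute_energy(1, 1, -0.5, defaults)

    def test_energy_non_decreasing_in_productivity(self):
        values = [
            compute_energy(10, 5, 1.0, ModelParams(c=c))
            for c in (1.0, 1.05, 1.5, 2.0, 3.0)
        ]
        assert np.all(np.diff(values) >= 0)


class TestSelectRecruit:
    def test_star_center_becomes_first_admin(self, rng):
        state = make_state([(0, i) for i in range(1, 6)], 6)
        assert select_recruit(state, rng) == 0

    def test_edgeless_society_has_no_candidate(self, rng):
        state = make_state([], 5)
        assert select_recruit(state, rng) is None

    def test_only_coordinated_laborers_eligible_after_first_admin(self, rng):
        # path 0-1-2-3 with admin 0: node 2 has equal degree to node 1 but
        # is not coordinated, so node 1 must be picked
        state = make_state([(0, 1), (1, 2), (2, 3)], 4)
        state.promote(0)
        assert select_recruit(state, rng) == 1

    def test_tie_break_is_seed_reproducible(self):
        state = make_state([(0, 1), (1, 2), (2, 3), (3, 0)], 4)  # 4-cycle
        picks = {
            select_recruit(state, np.random.default_rng(s)) for s in range(40)
        }
        assert picks <= {0, 1, 2, 3} and len(picks) > 1
        a = select_recruit(state, np.random.default_rng(7))
        b = select_recruit(state, np.random.default_rng(7))
        assert a == b


class TestExploration:
    def test_zero_probability_never_flips(self, rng):
        p = ModelParams(n=20, rho=0.3, p_e=0.0)
        state = build_network(p, rng)
        state.promote(0)
        before = state.admin_set
        assert exploration_step(state, p, rng) == 0
        assert state.admin_set == before

    def test_certain_flip_complements_admin_set(self, rng):
        p = ModelParams(n=20, rho=0.3, p_e=1.0)
        state = build_network(p, rng)
        state.promote(0)
        state.promote(5)
        n_flips = exploration_step(state, p, rng)
        assert n_flips == 20
        assert state.admin_set == set(range(20)) - {0, 5}

    def test_flip_rate_matches_binomial_mean(self, rng):
        p = ModelParams(n=100, rho=0.1, p_e=0.5)
        state = build_network(p, rng)
        flips = [exploration_step(state, p, rng) for _ in range(2000)]
        se = np.sqrt(100 * 0.25 / 2000)
        assert abs(np.mean(flips) - 50.0) < 4 * se

    def test_neighbour_counts_stay_consistent_under_flips(self, rng):
        p = ModelParams(n=30, rho=0.2, p_e=0.3)
        state = build_network(p, rng)
        for _ in range(30):
            exploration_step(state, p, rng)
            assert np.array_equal(
                state._admin_nbr, state.recount_admin_neighbors()
            )


class TestStep:
    def test_zero_threshold_disables_recruitment(self, rng):
        p = ModelParams(n=30, rho=0.2, epsilon=0.0, p_e=0.0)
        state = build_network(p, rng)
        for t in range(50):
            rec = step(state, None, p, rng, t=t)
            assert not rec.recruited
        assert state.n_admin == 0

    def test_first_shock_triggers_first_recruitment(self, rng):
        # with eps=1 the unshocked society sits exactly at the threshold,
        # so any positive shock (B > 0, almost sure) drops E/N below it
        p = ModelParams(n=50, rho=0.2)
        state = build_network(p, rng)
        rec = step(state, None, p, rng, t=1)
        assert rec.n_a == 0  # record shows the pre-recruitment state
        assert rec.recruited
        assert state.n_admin == 1  # promotion effective from the next step

    def test_promotion_affects_energy_only_next_step(self, rng):
        p = ModelParams(n=50, rho=0.2)
        state = build_network(p, rng)
        rec1 = step(state, None, p, rng, t=1)
        rec2 = step(state, rec1.e, p, rng, t=2)
        assert rec1.n_l == 50 and rec1.n_c == 0
        assert rec2.n_a == 1
        assert rec2.roc == pytest.approx(rec2.e - rec1.e)


class TestRunSimulation:
    def test_unconnected_society_stays_in_initial_state(self):
        res = run_simulation(ModelParams(n=50, rho=0.0, p_e=0.0, t_max=200, seed=3))
        assert res.censored and res.terminal_cause == CAUSE_CENSORED
        assert res.survival_time == 200
        assert np.all(res.columns["N_A"] == 0)
        assert np.all(res.columns["N_L"] == 50)

    def test_identical_seed_reproduces_identical_trajectory(self):
        p = ModelParams(n=100, t_max=300, p_e=0.01, seed=11)
        a, b = run_simulation(p), run_simulation(p)
        for key in a.columns:
            assert np.array_equal(a.columns[key], b.columns[key], equal_nan=True)

    def test_ratchet_conservation_and_collapse_endpoint(self):
        p = ModelParams(seed=1)  # reference configuration, p_e=0
        res = run_simulation(p)
        c = res.columns
        assert np.all(np.diff(c["N_A"]) >= 0)  # ratchet: no way back
        assert np.all(c["N_L"] + c["N_C"] + c["N_A"] == p.n)
        assert np.all(c["R"] >= 0) and np.all(c["R"] <= p.r_max)
        assert res.terminal_cause == CAUSE_COLLAPSE and not res.censored
        assert c["N_A"][-1] == p.n and c["E"][-1] == 0.0

    def test_roc_equals_energy_differences(self):
        res = run_simulation(ModelParams(n=100, t_max=200, seed=2))
        c = res.columns
        assert np.isnan(c["roc"][0])
        assert np.allclose(c["roc"][1:], np.diff(c["E"]))


def _fake_result(e_values, n_a_values):
    n = len(e_values)
    cols = {
        "t": np.arange(1, n + 1),
        "R": np.ones(n),
        "N_L": np.zeros(n, dtype=int),
        "N_C": np.zeros(n, dtype=int),
        "N_A": np.asarray(n_a_values),
        "E": np.asarray(e_values, dtype=float),
        "E_per_capita": np.asarray(e_values, dtype=float) / 10,
        "roc": np.full(n, np.nan),
        "n_flips": np.zeros(n, dtype=int),
        "recruited": np.zeros(n, dtype=bool),
    }
    return SimulationResult(
        params=ModelParams(n=10, t_max=max(n, 1)),
        columns=cols,
        survival_time=n,
        censored=True,
        terminal_cause=CAUSE_CENSORED,
    )


class TestRocCurve:
    def test_constant_energy_gives_flat_curve(self):
        res = _fake_result([5.0] * 40, np.arange(40))
        curve = roc_curve(res, window=7)
        assert np.allclose(curve["E_smooth"], 5.0)

    def test_window_one_is_identity(self):
        e = [1.0, 4.0, 2.0, 8.0]
        curve = roc_curve(_fake_result(e, [0, 1, 2, 3]), window=1)
        assert np.allclose(curve["E_smooth"], e)
        assert np.allclose(np.diff(curve["E_smooth"]), np.diff(e))

    def test_parabolic_energy_recovers_vertex(self):
        n_a = np.arange(101)
        e = -((n_a - 40.0) ** 2) + 2000.0
        curve = roc_curve(_fake_result(e, n_a), window=11)
        vertex = curve["N_A"][curve["E_smooth"].idxmax()]
        assert abs(vertex - 40) <= 5

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(_fake_result([], []), window=5)
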