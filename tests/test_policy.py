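import numpy as np
import pytest

import graywhale_sdp as g
from graywhale_sdp.habitat import CategoricalPreyField
from graywhale_sdp.policy import (A_FEED, A_LEAVE, A_WITHIN, N_FIXED,
                                  policy_probabilities, terminal_values)

from dp_oracle import TOY_L, TinySeason, make_instance, oracle, solve_dp, toy_area


class TestProbabilityRules:
    def test_argmax_tie_sharing(self):
        vals = np.array([1.0, 1.0, 0.5, 1.0 - 1e-9])
        pi = policy_probabilities(vals, "argmax", 1e-6, 0.0)
        np.testing.assert_allclose(pi, [1 / 3, 1 / 3, 0, 1 / 3])

    def test_softmax_sums_to_one_and_orders(self):
        vals = np.array([0.2, 0.5, 0.1, 0.4])
        pi = policy_probabilities(vals, "softmax", 0.0, 0.1)
        assert pi.sum() == pytest.approx(1.0)
        assert np.argmax(pi) == 1

    def test_class_softmax_travel_not_overweighted(self):
        # ten identical travel options must carry the weight of one class
        vals = np.concatenate([[0.0, 0.5, 0.5], np.full(10, 0.5)])
        pi = policy_probabilities(vals, "class_softmax", 0.0, 0.05)
        assert pi.sum() == pytest.approx(1.0)
        assert pi[N_FIXED:].sum() == pytest.approx(pi[A_FEED], abs=1e-12)
        np.testing.assert_allclose(pi[N_FIXED:], pi[N_FIXED], atol=1e-12)

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            policy_probabilities(np.zeros(4), "greedy", 0, 0)


class TestTerminalValues:
    def test_no_fetus_row_is_zero(self, bio):
        fat = np.linspace(0, 10000, 20)
        fetal = np.linspace(0, 1.3, 10)
        fn = g.FitnessFunction.from_variant("medium")
        term = terminal_values(fat, fetal, 12.7, fn, bio)
        np.testing.assert_allclose(term[:, 0], 0.0)

    def test_monotone_in_fat_and_max_corner(self, bio):
        fat = np.linspace(0, 10000, 20)
        fetal = np.linspace(0, 1.3, 10)
        fn = g.FitnessFunction.from_variant("medium")
        term = terminal_values(fat, fetal, 12.7, fn, bio)
        assert np.all(np.diff(term, axis=0) >= -1e-12)
        assert term[-1, -1] == term.max()


class TestBackwardOracle:
    def test_dp_matches_exhaustive_enumeration(self):
        """Randomized toy instances: grid DP equals recursive expectimax."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(8):
            inst = make_instance(rng)
            pol = solve_dp(inst)
            vb = oracle(inst)
            for t in range(inst.season.n_days + 1):
                for c in range(inst.area.n_cells):
                    for fi, f in enumerate(pol.fat_grids[0]):
                        for gi, gg in enumerate(pol.fetal_grid):
                            err = abs(pol.Vbar[0, t, c, fi, gi]
                                      - vb(t, float(f), float(gg), c))
                            worst = max(worst, err)
        assert worst < 1e-10

    def test_zero_prey_makes_leaving_optimal(self):
        area = toy_area(2)
        prey = CategoricalPreyField(
            {(c, "early"): (np.array([0.0, 0.0]), np.array([0.5, 0.5]))
             for c in (1, 2)}, 2)
        bio = g.BioenergeticParams(
            mass_coeff=1.0, mass_exp=0.0, metabolic_coeff_MJ=1.0,
            max_intake_coeff_MJ=1e9, fetal_growth_m_per_day=0.0,
            fetal_energy_MJ_per_m=0.0, catabolic_yield_MJ_per_kg=1.0,
            deposition_efficiency=1.0, reduced_growth_factor=1.0,
            fat_floor_frac=1.0, fat_max_frac=4.0, annual_mortality=0.0,
            foraging_fraction_mean=0.25, travel_MJ_per_km=1.0,
            inter_cell_distance_km=1.0, within_cell_distance_km=1.0)
        fn = g.FitnessFunction.from_variant("low")
        solver = g.PolicySolver(n_fat=5, n_fetal=2, n_lengths=1,
                                fetal_max_m=1.0, rule="argmax",
                                L_min=TOY_L, L_max=TOY_L)
        solver.fit(area, TinySeason(3), prey, bio=bio, fitness=fn)
        pol = solver.policy_
        # with nothing to eat and fat only falling, the value of any state
        # equals leaving immediately
        from graywhale_sdp.bioenergetics import survival_to_next_season

        for fi, f in enumerate(pol.fat_grids[0]):
            leave = float(survival_to_next_season(TOY_L, f, fn, bio)
                          * fn(f, pol.fetal_grid[0], TOY_L, bio))
            assert pol.Vbar[0, 0, 0, fi, 0] == pytest.approx(leave, abs=1e-10)

    def test_symmetric_cells_give_symmetric_values(self):
        area = toy_area(2)
        cat = (np.array([2.0, 4.0]), np.array([0.5, 0.5]))
        prey = CategoricalPreyField({(1, "early"): cat, (2, "early"): cat}, 2)
        bio = g.BioenergeticParams(
            mass_coeff=1.0, mass_exp=0.0, metabolic_coeff_MJ=1.0,
            max_intake_coeff_MJ=1e9, fetal_growth_m_per_day=0.0,
            fetal_energy_MJ_per_m=0.0, catabolic_yield_MJ_per_kg=1.0,
            deposition_efficiency=1.0, reduced_growth_factor=1.0,
            fat_floor_frac=1.0, fat_max_frac=4.0, annual_mortality=0.0,
            foraging_fraction_mean=0.25, travel_MJ_per_km=1.0,
            inter_cell_distance_km=1.0, within_cell_distance_km=1.0)
        solver = g.PolicySolver(n_fat=5, n_fetal=2, n_lengths=1,
                                fetal_max_m=1.0, rule="argmax",
                                L_min=TOY_L, L_max=TOY_L)
        solver.fit(area, TinySeason(4), prey, bio=bio, fitness="low")
        pol = solver.policy_
        np.testing.assert_allclose(pol.Vbar[0, :, 0], pol.Vbar[0, :, 1],
                                   atol=1e-12)
        pi1 = pol.action_probabilities(1, [0], [0], [1], [2.0], [0.0])
        pi2 = pol.action_probabilities(1, [0], [1], [1], [2.0], [0.0])
        np.testing.assert_allclose(pi1, pi2, atol=1e-12)

    def test_extra_prey_never_hurts(self):
        """Free disposal: enriching one cell cannot lower any value."""
        rng = np.random.default_rng(5)
        inst = make_instance(rng)
        pol = solve_dp(inst)
        richer = CategoricalPreyField(
            {k: (v[0] + 2.0, v[1]) for k, v in inst.prey._table.items()},
            inst.prey.n_categories)
        inst2 = type(inst)(inst.area, inst.season, richer, inst.bio,
                           inst.fitness, inst.n_fat, inst.n_fetal,
                           inst.fetal_max)
        pol2 = solve_dp(inst2)
        assert np.all(pol2.Vbar >= pol.Vbar - 1e-12)


class TestPolicyTable:
    def test_values_monotone_in_fat(self, small_policy, area, season, prey):
        # under the behavioral (softmax) rule the value is a mixture over
        # actions, so monotonicity only holds up to the behavioral-mixing
        # scale (a couple of temperatures) ...
        dv = np.diff(small_policy.Vbar, axis=3)
        assert np.all(dv >= -2 * small_policy.temperature)
        # ... while the optimal-value (argmax) table is exactly monotone
        solver = g.PolicySolver(n_fat=16, n_fetal=8, n_lengths=1,
                                rule="argmax")
        solver.fit(area, season, prey, fitness="low")
        assert np.all(np.diff(solver.policy_.Vbar, axis=3) >= 0.0)

    def test_probabilities_normalized_and_node_exact(self, small_policy):
        pol = small_policy
        day, li, ci, k = 60, 1, 9, 2
        fi, gi = 10, 6
        f = pol.fat_grids[li][fi]
        gg = pol.fetal_grid[gi]
        pi = pol.action_probabilities(day, [li], [ci], [k], [f], [gg])
        assert pi.shape == (1, pol.n_actions)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        vals = pol.action_values(day, [li], [ci], [k], [f], [gg])
        direct = policy_probabilities(vals, pol.rule, pol.epsilon,
                                      pol.temperature)
        np.testing.assert_allclose(pi, direct, atol=1e-12)

    def test_out_of_hull_state_clamped(self, small_policy):
        pol = small_policy
        big = pol.fat_grids[0][-1] * 2
        pi = pol.action_probabilities(10, [0], [3], [0], [big], [0.5])
        assert np.isfinite(pi).all()
        assert pi.sum() == pytest.approx(1.0)

    def test_save_load_roundtrip(self, small_policy, tmp_path):
        path = tmp_path / "policy"
        small_policy.save(path)
        again = g.PolicyTable.load(path)
        np.testing.assert_array_equal(again.Vbar, small_policy.Vbar)
        np.testing.assert_array_equal(again.lengths, small_policy.lengths)
        assert again.rule == small_policy.rule
        assert again.config_hash() == small_policy.config_hash()
        pi1 = small_policy.action_probabilities(40, [1], [5], [1], [3000.0],
                                                [0.4])
        pi2 = again.action_probabilities(40, [1], [5], [1], [3000.0], [0.4])
        np.testing.assert_allclose(pi1, pi2)

    def test_nearest_length_selection(self, small_policy):
        idx = small_policy.length_index(np.array([11.0, 12.4, 13.9]))
        assert idx[0] == 0 and idx[-1] == small_policy.n_lengths - 1
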