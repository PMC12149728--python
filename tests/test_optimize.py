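import numpy as np
import pytest

from shieldplan import (
    CombinationSet,
    PenaltyConfig,
    ScenarioSet,
    StructurePenalty,
    assemble_problem,
    build_scenario_matrices,
    default_penalties,
    generate_phantom,
    objective_value,
    solve,
    tune_target_weight,
    voxelwise_worstcase,
)
from helpers import make_dose_matrix, grid_search_minimum, robust_objective_batch


def toy_problem():
    """2 combinations x 4 dose points (2 target, 2 OAR), printed matrix."""
    values = [[1.0, 0.2],     # target
              [0.3, 1.1],     # target
              [0.5, 0.1],     # oar
              [0.1, 0.6]]     # oar (Gy/s)
    roles = ["ctv", "ctv", "contra", "contra"]
    mat = make_dose_matrix(values, roles)
    pens = PenaltyConfig({
        "ctv": StructurePenalty(lower=10.0, upper=14.0, q_low=1.0, q_high=0.5),
        "contra": StructurePenalty(upper=4.0, w_high=0.2, q_high=1.0),
    })
    return [mat], pens


def oracle_for(problem, upper=50.0, step=0.01):
    def batch(ts):
        return robust_objective_batch(
            ts, problem.matrices, problem.lower, problem.upper,
            problem.w_low, problem.w_high, problem.q_low, problem.q_high,
            problem.lambda_worst, problem.mean_weight)
    return grid_search_minimum(batch, problem.n_combos, upper, step)


class TestAssemble:
    def test_singleton_scenario_scales_objective_but_not_argmin(self):
        mats, pens = toy_problem()
        p1 = assemble_problem(mats, pens, lambda_worst=1.0, mean_weight=1.0)
        p2 = assemble_problem(mats, pens, lambda_worst=0.0, mean_weight=1.0)
        s1, s2 = solve(p1), solve(p2)
        assert np.allclose(s1.dwell_times, s2.dwell_times, atol=1e-6)
        assert s1.objective == pytest.approx(2.0 * s2.objective, rel=1e-8, abs=1e-10)

    def test_zero_weight_structure_contributes_nothing(self):
        mats, _ = toy_problem()
        pens_off = PenaltyConfig({
            "ctv": StructurePenalty(lower=10.0, q_low=1.0),
            "contra": StructurePenalty(upper=4.0),     # all weights zero
        })
        pens_on = PenaltyConfig({
            "ctv": StructurePenalty(lower=10.0, q_low=1.0),
            "contra": StructurePenalty(upper=4.0, q_high=3.0),
        })
        t = np.array([5.0, 7.0])
        obj_off = objective_value(t, assemble_problem(mats, pens_off))[0]
        obj_on = objective_value(t, assemble_problem(mats, pens_on))[0]
        ctv_only = objective_value(
            t, assemble_problem(mats, PenaltyConfig({
                "ctv": StructurePenalty(lower=10.0, q_low=1.0),
                "contra": StructurePenalty(),
            })))[0]
        assert obj_off == pytest.approx(ctv_only)
        assert obj_on > obj_off

    def test_constraint_counts_on_two_structure_toy(self):
        # 4 lower rows; only the 2 CTV + 2 contra upper bounds are finite
        mats, pens = toy_problem()
        counts = assemble_problem(mats, pens).constraint_counts()
        assert counts == {"lower": 4, "upper": 4, "scenario_penalty": 1,
                          "worst_case": 1, "total": 10}
        pens_nou = PenaltyConfig({
            "ctv": StructurePenalty(lower=10.0, q_low=1.0),
            "contra": StructurePenalty(upper=4.0, q_high=1.0),
        })
        counts = assemble_problem(mats, pens_nou).constraint_counts()
        assert counts["upper"] == 2          # unbounded CTV drops its excess rows

    def test_missing_structure_and_negative_weight_rejected(self):
        mats, pens = toy_problem()
        with pytest.raises(ValueError, match="contra"):
            assemble_problem(mats, PenaltyConfig({"ctv": StructurePenalty(
                lower=10.0, q_low=1.0)}))
        with pytest.raises(ValueError):
            assemble_problem(mats, pens, lambda_worst=-1.0)
        with pytest.raises(ValueError):
            assemble_problem(mats, pens, lambda_worst=0.0, mean_weight=0.0)


class TestSolve:
    def test_all_zero_weights_give_zero_plan(self):
        mats, _ = toy_problem()
        pens = PenaltyConfig({"ctv": StructurePenalty(lower=10.0),
                              "contra": StructurePenalty()})
        sol = solve(assemble_problem(mats, pens))
        assert sol.objective == 0.0
        assert np.allclose(sol.dwell_times, 0.0)

    def test_closed_form_single_point_single_combo(self):
        # quadratic lower penalty only: shortfall driven to zero at t* = L/d
        mat = make_dose_matrix([[1.0]], ["ctv"])
        pens = PenaltyConfig({"ctv": StructurePenalty(lower=10.0, q_low=1.0)})
        sol = solve(assemble_problem([mat], pens))
        assert sol.dwell_times[0] == pytest.approx(10.0, rel=1e-6)
        assert sol.objective == pytest.approx(0.0, abs=1e-10)

    def test_toy_objective_matches_grid_search(self):
        mats, pens = toy_problem()
        problem = assemble_problem(mats, pens)
        sol = solve(problem)
        _, f_grid = oracle_for(problem)
        assert sol.objective <= f_grid + 1e-9
        assert f_grid - sol.objective <= 1e-3 * (1.0 + abs(f_grid))

    def test_positive_parts_reported_without_slack_inflation(self):
        mats, pens = toy_problem()
        problem = assemble_problem(mats, pens)
        sol = solve(problem)
        dose = problem.d_gy[0] @ sol.dwell_times
        assert np.allclose(sol.shortfalls[0], np.maximum(problem.lower - dose, 0.0),
                           atol=1e-10)
        assert np.allclose(sol.excesses[0],
                           np.where(np.isfinite(problem.upper),
                                    np.maximum(dose - problem.upper, 0.0), 0.0),
                           atol=1e-10)

    def test_scale_covariance(self):
        mats, pens = toy_problem()
        problem = assemble_problem(mats, pens)
        sol = solve(problem)
        scaled = [make_dose_matrix(m.values / 100.0 * 3.0,
                                   m.row_role) for m in mats]
        sol3 = solve(assemble_problem(scaled, pens))
        assert np.allclose(sol3.dwell_times, sol.dwell_times / 3.0, atol=1e-6)
        assert sol3.objective == pytest.approx(sol.objective, rel=1e-6, abs=1e-9)

    def test_repeated_solves_deterministic(self):
        mats, pens = toy_problem()
        a = solve(assemble_problem(mats, pens))
        b = solve(assemble_problem(mats, pens))
        assert a.objective == b.objective
        assert np.array_equal(a.dwell_times, b.dwell_times)


class TestObjectiveValue:
    def test_zero_plan_penalty_is_full_shortfall(self):
        mats, pens = toy_problem()
        problem = assemble_problem(mats, pens)
        _, z, _ = objective_value(np.zeros(2), problem)
        expected = 2 * (1.0 * 10.0 ** 2)        # two CTV points, q_low * L^2
        assert z[0] == pytest.approx(expected)

    def test_singleton_scenario_worst_equals_only_scenario(self):
        mats, pens = toy_problem()
        problem = assemble_problem(mats, pens)
        _, z, z_w = objective_value(np.array([3.0, 4.0]), problem)
        assert z_w == z[0]

    def test_random_feasible_points_never_beat_solver(self):
        mats, pens = toy_problem()
        problem = assemble_problem(mats, pens)
        sol = solve(problem)
        rng = np.random.default_rng(5)
        ts = rng.uniform(0.0, 30.0, size=(1000, 2))
        objs = np.array([objective_value(t, problem)[0] for t in ts])
        assert np.all(objs >= sol.objective - 1e-9)

    def test_negative_dwell_times_rejected(self):
        mats, pens = toy_problem()
        with pytest.raises(ValueError):
            objective_value(np.array([-1.0, 0.0]), assemble_problem(mats, pens))


class TestVoxelwiseWorstCase:
    def two_scenario_mats(self):
        a = make_dose_matrix([[1.0, 2.0], [3.0, 4.0]], ["ctv", "contra"])
        b = make_dose_matrix([[0.5, 2.5], [3.5, 3.0]], ["ctv", "contra"], label="r+5")
        return [a, b]

    def test_elementwise_min_max_by_hand(self):
        comp = voxelwise_worstcase(self.two_scenario_mats())
        # target row: elementwise min; OAR row: elementwise max (Gy/s * 100)
        assert np.allclose(comp.values[0], np.array([0.5, 2.0]) * 100.0)
        assert np.allclose(comp.values[1], np.array([3.5, 4.0]) * 100.0)

    def test_identical_scenarios_collapse_to_any(self):
        a = make_dose_matrix([[1.0, 2.0], [3.0, 4.0]], ["ctv", "contra"])
        b = make_dose_matrix([[1.0, 2.0], [3.0, 4.0]], ["ctv", "contra"], label="x")
        comp = voxelwise_worstcase([a, b])
        assert np.array_equal(comp.values, a.values)

    def test_composite_brackets_nominal(self, planned_phantom, source_model):
        ph, combos = planned_phantom["phantom"], planned_phantom["combos"]
        mats = build_scenario_matrices(ph, combos, ScenarioSet.rotation(5.0),
                                       source_model)
        comp = voxelwise_worstcase(mats)
        nominal = mats[0]
        tgt = comp.rows_for("ctv")
        assert np.all(comp.values[tgt] <= nominal.values[tgt])
        assert np.all(comp.values[~tgt] >= nominal.values[~tgt])

    def test_single_scenario_and_missing_role_rejected(self):
        mats = self.two_scenario_mats()
        with pytest.raises(ValueError):
            voxelwise_worstcase(mats[:1])
        with pytest.raises(ValueError, match="contra"):
            voxelwise_worstcase(mats, roles={"ctv": "target"})


class TestRobustness:
    def test_robust_dominance_on_phantom(self, small_cohort, applicator, source_model):
        phantom = generate_phantom(small_cohort, 1, applicator)
        combos = CombinationSet.build(applicator)
        mats_r = build_scenario_matrices(phantom, combos, ScenarioSet.rotation(5.0),
                                         source_model)
        prob_r = assemble_problem(mats_r, default_penalties())
        prob_q = assemble_problem(mats_r[:1], default_penalties())
        t_r = solve(prob_r).dwell_times
        t_q = solve(prob_q).dwell_times
        assert objective_value(t_r, prob_r)[0] <= objective_value(t_q, prob_r)[0] + 1e-9

    def test_minimax_toy_matches_grid_search(self):
        a = make_dose_matrix([[1.0, 0.3], [0.2, 0.9]], ["ctv", "contra"])
        b = make_dose_matrix([[0.7, 0.5], [0.4, 0.6]], ["ctv", "contra"], label="r+5")
        c = make_dose_matrix([[1.2, 0.2], [0.1, 1.1]], ["ctv", "contra"], label="r-5")
        pens = PenaltyConfig({
            "ctv": StructurePenalty(lower=8.0, q_low=1.0),
            "contra": StructurePenalty(upper=3.0, q_high=2.0),
        })
        problem = assemble_problem([a, b, c], pens)
        sol = solve(problem)
        _, f_grid = oracle_for(problem)
        assert sol.objective <= f_grid + 1e-9
        assert f_grid - sol.objective <= 1e-3 * (1.0 + abs(f_grid))


class TestWeightTuning:
    def test_conforming_config_returned_unchanged(self, planned_phantom):
        problem = planned_phantom["problem"]
        eval_mat = planned_phantom["matrices"][0]
        # choose a tolerance generous enough that the current plan conforms
        res = tune_target_weight(problem, eval_mat, prescription=10.0, tol=np.inf)
        assert res.converged
        assert res.penalties is problem.penalties
        assert len(res.trajectory) == 1

    def test_doubling_target_weight_never_decreases_d90(self):
        from shieldplan.evaluate import cumulative_dvh, dose_at_volume_percent
        mats, pens = toy_problem()
        d90s = []
        for factor in (1.0, 2.0, 4.0):
            problem = assemble_problem(mats, pens.scaled(factor, 1.0))
            sol = solve(problem)
            dose = mats[0].values[mats[0].rows_for("ctv")] @ sol.dwell_times / 100.0
            d90s.append(dose_at_volume_percent(cumulative_dvh(dose, 0.001), 90.0))
        assert d90s[0] <= d90s[1] + 1e-9 <= d90s[2] + 2e-9

    def test_tuning_moves_d90_toward_prescription(self):
        mats, pens = toy_problem()
        problem = assemble_problem(mats, pens)
        res = tune_target_weight(problem, mats[0], prescription=10.0,
                                 max_iter=10, tol=0.02)
        assert res.converged
        assert abs(res.trajectory[-1][0] - 10.0) / 10.0 <= 0.25  # moved close
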