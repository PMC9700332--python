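"""Subpath constraints, interval flows, and imperfect-flow models."""

import pytest

from flowdec import (
    Constraint,
    FlowNetwork,
    GraphStructureError,
    IntervalFlowNetwork,
    SolverConfig,
    add_path_constraints,
    build_bounded_error_model,
    build_inexact_model,
    build_kfd_model,
    build_min_error_model,
    extract_decomposition,
    solve_mfd,
    solve_model,
    validate_constraints,
    validate_decomposition,
)
from flowdec.oracle import oracle_min_error_at_k, oracle_min_k

from conftest import planted


def run(model, config=None):
    return solve_model(model, config), model


class TestPathConstraints:
    def test_g5_with_subpath_constraint(self, g5):
        c = Constraint("c", [[("a", "b"), ("b", "t")]])
        model = add_path_constraints(build_kfd_model(g5, 3), [c])
        outcome = solve_model(model)
        assert outcome.status == "optimal"
        dec = extract_decomposition(model, outcome)
        assert validate_constraints(dec, [c]).ok
        assert validate_decomposition(g5, dec).ok

    def test_two_leg_constraint_infeasible_on_diamond(self, diamond):
        c = Constraint("c", [[("s", "a")], [("b", "t")]])
        for k in range(1, 5):
            model = add_path_constraints(build_kfd_model(diamond, k), [c])
            assert solve_model(model).status == "infeasible"

    def test_empty_constraint_list_is_identity(self, g5):
        model = build_kfd_model(g5, 3)
        rows_before = model.lp.n_rows
        add_path_constraints(model, [])
        assert model.lp.n_rows == rows_before

    def test_unknown_edge_is_a_structural_error(self, g5):
        c = Constraint("c", [[("b", "a")]])
        with pytest.raises(GraphStructureError, match="absent"):
            add_path_constraints(build_kfd_model(g5, 3), [c])


class TestInexact:
    def test_degenerate_intervals_match_exact_feasibility(self, g5):
        iv = IntervalFlowNetwork("g5d", list(g5.nodes),
                                 {e: (f, f) for e, f in g5.flows.items()})
        for k in (2, 3, 4):
            exact = solve_model(build_kfd_model(g5, k)).status
            inexact = solve_model(build_inexact_model(iv, k)).status
            assert exact == inexact

    def test_single_edge_interval_weight_in_range(self):
        iv = IntervalFlowNetwork("e", ["s", "t"], {("s", "t"): (3, 7)})
        outcome, model = run(build_inexact_model(iv, 1))
        assert outcome.status == "optimal"
        dec = extract_decomposition(model, outcome)
        assert 3 <= dec.weights[0] <= 7

    def test_interval_relaxation_reduces_k(self, g5_intervals):
        outcome, model = run(build_inexact_model(g5_intervals, 2))
        assert outcome.status == "optimal"
        dec = extract_decomposition(model, outcome)
        assert validate_decomposition(None, dec, "interval", g5_intervals).ok


class TestBoundedError:
    def test_b0_collapses_to_exact(self, g5):
        for k in (2, 3):
            exact = solve_model(build_kfd_model(g5, k)).status
            bounded = solve_model(build_bounded_error_model(g5, k, 0)).status
            assert exact == bounded

    def test_two_lane_examples(self, two_lane):
        assert solve_model(build_bounded_error_model(two_lane, 1, 2)).status == "optimal"
        assert solve_model(build_bounded_error_model(two_lane, 1, 1)).status == "infeasible"
        assert solve_model(build_bounded_error_model(two_lane, 2, 1)).status == "optimal"

    def test_negative_bound_rejected(self, g5):
        with pytest.raises(ValueError, match="B must be"):
            build_bounded_error_model(g5, 1, -1)

    def test_feasibility_monotone_in_b(self):
        from flowdec import perturb_to_imperfect
        for seed in range(6):
            inst = planted(seed)
            net = perturb_to_imperfect(inst, 0.15)
            feasible_at = {}
            for B in (0, 1, 2, 3):
                res = oracle_min_k(net, mode="bounded", B=B)
                feasible_at[B] = res.min_k
            ks = [feasible_at[B] for B in (0, 1, 2, 3) if feasible_at[B] is not None]
            assert ks == sorted(ks, reverse=True)  # larger B never needs more paths


class TestMinError:
    def test_zero_objective_at_exact_minimum(self, g5):
        k = solve_mfd(g5).min_k
        outcome, _ = run(build_min_error_model(g5, k))
        assert outcome.status == "optimal"
        assert outcome.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_chain_single_path_objective_one(self, chain):
        outcome, model = run(build_min_error_model(chain, 1))
        assert outcome.objective_value == pytest.approx(1.0, abs=1e-6)
        dec = extract_decomposition(model, outcome)
        assert dec.weights[0] in (5, 6)

    def test_two_lane_k1_objective_two(self, two_lane):
        outcome, model = run(build_min_error_model(two_lane, 1))
        assert outcome.objective_value == pytest.approx(2.0, abs=1e-6)
        dec = extract_decomposition(model, outcome)
        assert [p.nodes for p in dec.paths] == [("s", "a", "t")]
        assert dec.weights == [3]

    def test_per_k_objective_matches_brute_force(self):
        from flowdec import perturb_to_imperfect
        cfg = SolverConfig(symmetry_breaking=True)
        for seed in range(4):
            inst = planted(seed, n_nodes=6)
            net = perturb_to_imperfect(inst, 0.2)
            for k in (1, 2, 3):
                outcome, _ = run(build_min_error_model(net, k, cfg), cfg)
                assert outcome.status == "optimal"
                best = oracle_min_error_at_k(net, k, distinct=False)
                assert outcome.objective_value == pytest.approx(best[0], abs=1e-6)
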