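"""Planted-instance generator and perturbation procedures."""

import pytest

from flowdec import (
    GeneratorConfig,
    InstanceExcluded,
    generate_planted_instance,
    perturb_to_imperfect,
    perturb_to_intervals,
    sample_subpath_constraints,
    solve_mfd,
    validate_constraints,
    validate_decomposition,
)
from flowdec.synth import _round_half_up, interval_flow_feasible

from conftest import planted


class TestGenerator:
    def test_superposition_identity(self):
        for seed in range(10):
            inst = planted(seed, k_planted=3)
            expected = {}
            for p, w in zip(inst.truth_paths, inst.truth_weights):
                for e in p.edges:
                    expected[e] = expected.get(e, 0) + w
            assert inst.network.flows == expected

    def test_deterministic_given_seed(self):
        a = generate_planted_instance(GeneratorConfig(seed=42))
        b = generate_planted_instance(GeneratorConfig(seed=42))
        assert a.network.flows == b.network.flows
        assert [p.nodes for p in a.truth_paths] == [p.nodes for p in b.truth_paths]
        assert a.truth_weights == b.truth_weights

    def test_k1_gives_single_path(self):
        inst = planted(0, k_planted=1)
        assert solve_mfd(inst.network).min_k == 1

    def test_planted_k_upper_bounds_minimum(self):
        for seed in range(10):
            inst = planted(seed)
            res = solve_mfd(inst.network)
            assert res.min_k <= inst.k_planted
            assert validate_decomposition(inst.network, res.decomposition).ok

    def test_nontrivial_graphs_when_k_above_one(self):
        for seed in range(10):
            inst = planted(seed, k_planted=3)
            branching = any(
                len(inst.network.out_edges(v)) > 1 or len(inst.network.in_edges(v)) > 1
                for v in inst.network.nodes
            )
            assert branching

    def test_truth_decomposition_validates(self):
        for seed in range(5):
            inst = planted(seed)
            assert validate_decomposition(inst.network,
                                          inst.truth_decomposition()).ok

    def test_lognormal_weights_are_positive_integers(self):
        inst = generate_planted_instance(
            GeneratorConfig(weight_scheme="lognormal", seed=5))
        assert all(isinstance(w, int) and w >= 1 for w in inst.truth_weights)


class TestIntervalPerturbation:
    def test_eps_zero_intervals_are_exact_tolerance_bands(self):
        cfg = GeneratorConfig(n_nodes=8, k_planted=3, weight_scheme="uniform",
                              weight_lo=1, weight_hi=9, epsilon=0.0, seed=3)
        inst = generate_planted_instance(cfg)
        iv = perturb_to_intervals(inst, cfg)
        for e, f in inst.network.flows.items():
            assert iv.intervals[e] == (_round_half_up(0.9 * f),
                                       _round_half_up(1.1 * f))

    def test_eps_zero_contains_true_flow_at_f_ge_5(self):
        for seed in range(8):
            cfg = GeneratorConfig(n_nodes=7, k_planted=2, weight_scheme="uniform",
                                  weight_lo=3, weight_hi=9, epsilon=0.0, seed=seed)
            inst = generate_planted_instance(cfg)
            iv = perturb_to_intervals(inst, cfg)
            for e, f in inst.network.flows.items():
                if f >= 5:
                    lo, hi = iv.intervals[e]
                    assert lo <= f <= hi

    def test_deterministic_given_seed(self):
        inst = planted(4)
        a = perturb_to_intervals(inst)
        b = perturb_to_intervals(inst)
        assert a.intervals == b.intervals

    def test_generated_instances_are_flow_feasible(self):
        for seed in range(8):
            inst = planted(seed)
            assert interval_flow_feasible(perturb_to_intervals(inst))


class TestSubpathSampling:
    def test_skip_signal_with_too_few_paths(self):
        inst = planted(0, k_planted=3)
        cfg = GeneratorConfig(n_constraints=4, seed=0)
        with pytest.raises(InstanceExcluded):
            sample_subpath_constraints(inst, cfg)

    def test_truth_decomposition_satisfies_sampled_constraints(self):
        for seed in range(8):
            inst = planted(seed, n_nodes=9, k_planted=4)
            cfg = inst.config
            try:
                cons = sample_subpath_constraints(inst, cfg)
            except InstanceExcluded:
                continue
            assert len(cons) == cfg.n_constraints
            assert validate_constraints(inst.truth_decomposition(), cons,
                                        inst.network).ok

    def test_junction_free_path_contributes_whole_path(self):
        inst = planted(0, k_planted=1)
        cfg = GeneratorConfig(n_constraints=1, seed=0)
        cons = sample_subpath_constraints(inst, cfg)
        leg = cons[0].legs[0]
        assert len(leg) == len(inst.truth_paths[0].edges)


class TestImperfectPerturbation:
    def test_zero_noise_is_identity(self):
        inst = planted(2)
        net = perturb_to_imperfect(inst, 0.0)
        assert net.flows == inst.network.flows

    def test_deterministic_given_seed(self):
        inst = planted(2)
        assert (perturb_to_imperfect(inst, 0.2).flows
                == perturb_to_imperfect(inst, 0.2).flows)

    def test_flows_stay_nonnegative(self):
        for seed in range(6):
            inst = planted(seed)
            net = perturb_to_imperfect(inst, 0.8)
            assert all(f >= 0 for f in net.flows.values())
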