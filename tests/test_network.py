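"""Data model, file I/O, normalization and validator behaviour."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from flowdec import (
    Constraint,
    Decomposition,
    FlowNetwork,
    GraphStructureError,
    Path,
    check_flow_conservation,
    ensure_single_source_sink,
    lower_bound_k,
    read_graph_file,
    unit_decomposition,
    validate_constraints,
    validate_decomposition,
    write_graph_file,
)
from flowdec.graphio import GraphFormatError, read_constraints_file
from flowdec.oracle import oracle_min_k

from conftest import planted


class TestParsing:
    def test_single_graph(self):
        nets = read_graph_file(io.StringIO("# graph 0\n2\n0 1 5\n"))
        assert len(nets) == 1
        assert nets[0].graph_id == "graph 0"
        assert nets[0].flows == {("0", "1"): 5}

    def test_two_blocks_in_order(self):
        text = "# first\n2\n0 1 5\n# second\n3\n0 1 2\n1 2 2\n"
        nets = read_graph_file(io.StringIO(text))
        assert [n.graph_id for n in nets] == ["first", "second"]

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            read_graph_file(io.StringIO("# g\n2\n0 1 -3\n"))

    def test_duplicate_edge_rejected(self):
        with pytest.raises(GraphFormatError, match="duplicate"):
            read_graph_file(io.StringIO("# g\n2\n0 1 3\n0 1 4\n"))

    def test_cycle_rejected_naming_a_node(self):
        with pytest.raises(GraphStructureError, match="cycle"):
            read_graph_file(io.StringIO("# g\n2\n0 1 3\n1 0 3\n"))

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(GraphFormatError, match="line 3"):
            read_graph_file(io.StringIO("# g\n2\n0 1\n"))

    def test_zero_flow_edges_dropped_by_default(self):
        nets = read_graph_file(io.StringIO("# g\n3\n0 1 5\n1 2 5\n0 2 0\n"))
        assert ("0", "2") not in nets[0].flows
        kept = read_graph_file(io.StringIO("# g\n3\n0 1 5\n1 2 5\n0 2 0\n"),
                               keep_zero_edges=True)
        assert kept[0].flows[("0", "2")] == 0

    def test_interval_dialect_and_bad_bounds(self):
        nets = read_graph_file(io.StringIO("# g\n2\n0 1 3 7\n"), dialect="interval")
        assert nets[0].intervals == {("0", "1"): (3, 7)}
        with pytest.raises(ValueError, match="high < low"):
            read_graph_file(io.StringIO("# g\n2\n0 1 7 3\n"), dialect="interval")

    def test_constraints_file_with_legs(self):
        text = "# g\na b t\ns a ; b t\n"
        per_graph = read_constraints_file(io.StringIO(text))
        cons = per_graph["g"]
        assert cons[0].legs == [[("a", "b"), ("b", "t")]]
        assert cons[1].legs == [[("s", "a")], [("b", "t")]]
        assert cons[1].size == 2


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["exact", "interval"])
    def test_round_trip_identity(self, dialect, g5, g5_intervals):
        net = g5 if dialect == "exact" else g5_intervals
        buf = io.StringIO()
        write_graph_file([net], buf, dialect)
        buf.seek(0)
        back = read_graph_file(buf, dialect)[0]
        if dialect == "exact":
            assert back.flows == net.flows
        else:
            assert back.intervals == net.intervals
        assert back.graph_id == net.graph_id

    def test_empty_list_writes_nothing(self):
        buf = io.StringIO()
        write_graph_file([], buf)
        assert buf.getvalue() == ""

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_on_random_instances(self, seed):
        net = planted(seed).network
        buf = io.StringIO()
        write_graph_file([net], buf)
        buf.seek(0)
        assert read_graph_file(buf)[0].flows == net.flows


class TestNormalization:
    def test_two_sources_get_super_source(self):
        net = FlowNetwork("m", ["a", "b", "t"], {("a", "t"): 3, ("b", "t"): 4})
        fixed = ensure_single_source_sink(net)
        s = fixed.source
        assert fixed.flows[(s, "a")] == 3 and fixed.flows[(s, "b")] == 4

    def test_single_source_sink_unchanged(self, g5):
        assert ensure_single_source_sink(g5) is g5

    def test_two_sources_and_two_sinks(self):
        net = FlowNetwork(
            "m", ["a", "b", "c", "d"],
            {("a", "c"): 1, ("b", "d"): 2},
        )
        fixed = ensure_single_source_sink(net)
        assert len(fixed.nodes) == 6
        assert check_flow_conservation(fixed).ok

    def test_empty_graph_is_an_error(self):
        net = FlowNetwork("empty", ["a"], {})
        with pytest.raises(GraphStructureError):
            ensure_single_source_sink(net)


class TestConservation:
    def test_g5_conserves(self, g5):
        assert check_flow_conservation(g5).ok

    def test_chain_imbalance(self, chain):
        report = check_flow_conservation(chain)
        assert not report.ok
        assert report.node_imbalance["a"] == -1

    def test_single_edge_has_no_internal_nodes(self):
        net = FlowNetwork("e", ["s", "t"], {("s", "t"): 5})
        assert check_flow_conservation(net).ok


class TestValidators:
    def test_exact_superposition(self, g5):
        dec = Decomposition(
            [Path(("s", "a", "t")), Path(("s", "a", "b", "t")), Path(("s", "b", "t"))],
            [4, 2, 7],
        )
        assert validate_decomposition(g5, dec).ok

    def test_residual_reported(self):
        net = FlowNetwork("e", ["s", "t"], {("s", "t"): 5})
        dec = Decomposition([Path(("s", "t"))], [4])
        report = validate_decomposition(net, dec)
        assert not report.ok
        assert report.edge_residuals[("s", "t")] == -1

    def test_structural_error_names_the_path(self, g5):
        dec = Decomposition([Path(("a", "t"))], [4])
        with pytest.raises(GraphStructureError, match="a-t"):
            validate_decomposition(g5, dec)

    def test_interval_mode(self, g5_intervals):
        dec = Decomposition([Path(("s", "a", "t")), Path(("s", "b", "t"))], [4, 7])
        assert validate_decomposition(None, dec, "interval", g5_intervals).ok

    def test_single_leg_constraint_containment(self):
        dec = Decomposition([Path(("s", "a", "b", "t"))], [1])
        c = Constraint("c", [[("a", "b"), ("b", "t")]])
        assert validate_constraints(dec, [c]).ok

    def test_missing_edge_constraint_violated(self):
        dec = Decomposition([Path(("s", "a", "t")), Path(("s", "b", "t"))], [1, 1])
        c = Constraint("c", [[("a", "b")]])
        report = validate_constraints(dec, [c])
        assert report.violated_constraints == ["c"]

    def test_two_leg_constraint_needs_one_covering_path(self):
        dec = Decomposition([Path(("s", "a", "t")), Path(("s", "b", "t"))], [1, 1])
        c = Constraint("c", [[("s", "a")], [("b", "t")]])
        assert not validate_constraints(dec, [c]).ok

    def test_single_leg_agrees_with_subsequence_check(self):
        # containment of all edges in a simple path implies consecutiveness
        for seed in range(10):
            inst = planted(seed, k_planted=3)
            dec = inst.truth_decomposition()
            for p in dec.paths:
                frag = p.nodes[: max(2, len(p.nodes) - 1)]
                c = Constraint("c", [list(zip(frag, frag[1:]))])
                ok = validate_constraints(dec, [c]).ok
                contiguous = any(
                    q.nodes[i:i + len(frag)] == frag
                    for q in dec.paths for i in range(len(q.nodes))
                )
                assert ok == contiguous


class TestLowerBound:
    @pytest.mark.parametrize("fixture,expected", [
        ("single", 1), ("diamond", 2), ("g5", 2),
    ])
    def test_examples(self, fixture, expected, diamond, g5):
        if fixture == "single":
            net = FlowNetwork("e", ["s", "t"], {("s", "t"): 5})
        elif fixture == "diamond":
            net = diamond
        else:
            net = g5
        assert lower_bound_k(net) == expected

    def test_never_exceeds_oracle_minimum(self):
        for seed in range(15):
            net = planted(seed).network
            assert lower_bound_k(net) <= oracle_min_k(net).min_k


class TestUnitDecomposition:
    def test_unit_weight_decomposition_validates(self):
        for seed in range(10):
            net = planted(seed).network
            dec = unit_decomposition(net)
            assert len(dec.paths) == net.total_flow
            assert validate_decomposition(net, dec).ok
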