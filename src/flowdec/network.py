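"""Flow-network data model and validators.

A flow network here is a DAG with a unique source (in-degree 0) and unique
sink (out-degree 0) carrying a nonnegative integer value on every edge.  When
the values satisfy conservation at every internal node the network is a flow
in the classical sense and admits a decomposition into weighted source-to-sink
paths; the solvers in :mod:`flowdec.ilp` and :mod:`flowdec.variants` search
for minimum-cardinality decompositions and relaxations thereof.

Node identifiers are opaque strings; integer ids from input files are kept
as written.  Parallel edges are rejected: every model variable downstream is
indexed by the ordered pair (tail, head).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "FlowNetwork",
    "IntervalFlowNetwork",
    "Path",
    "Decomposition",
    "Constraint",
    "ValidationReport",
    "GraphStructureError",
    "ensure_single_source_sink",
    "check_flow_conservation",
    "validate_decomposition",
    "validate_constraints",
    "lower_bound_k",
    "unit_decomposition",
]

Node = str
Edge = tuple[Node, Node]

SUPER_SOURCE = "__source__"
SUPER_SINK = "__sink__"


class GraphStructureError(ValueError):
    """The graph violates a structural requirement (cycle, no source/sink, ...)."""


def _check_dag(nodes: Iterable[Node], edges: Iterable[Edge]) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise GraphStructureError(
            f"graph contains a directed cycle through node {cyc[0][0]!r}"
        )


@dataclass
class FlowNetwork:
    """DAG with a nonnegative integer flow value on each edge.

    ``flows`` maps each ordered pair (tail, head) to its value; insertion
    order is the canonical edge order.  ``conserving`` is a cached flag set
    by :func:`check_flow_conservation`.
    """

    graph_id: str
    nodes: list[Node]
    flows: dict[Edge, int]
    conserving: Optional[bool] = None

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for (u, v), f in self.flows.items():
            if u not in known or v not in known:
                raise GraphStructureError(f"edge ({u!r}, {v!r}) uses an unknown node")
            if u == v:
                raise GraphStructureError(f"self-loop on node {u!r}")
            if f < 0:
                raise ValueError(f"negative flow {f} on edge ({u!r}, {v!r})")
        _check_dag(self.nodes, self.flows)

    # -- structural accessors -------------------------------------------------

    @property
    def edges(self) -> list[Edge]:
        return list(self.flows)

    def out_edges(self, u: Node) -> list[Edge]:
        return [e for e in self.flows if e[0] == u]

    def in_edges(self, v: Node) -> list[Edge]:
        return [e for e in self.flows if e[1] == v]

    def _degree_zero(self) -> tuple[list[Node], list[Node]]:
        # isolated nodes (possible after zero-flow edges are dropped) are
        # ignored when locating the source and sink
        has_in = {v for (_, v) in self.flows}
        has_out = {u for (u, _) in self.flows}
        incident = has_in | has_out
        sources = [n for n in self.nodes if n in incident and n not in has_in]
        sinks = [n for n in self.nodes if n in incident and n not in has_out]
        return sources, sinks

    @property
    def source(self) -> Node:
        sources, _ = self._degree_zero()
        if len(sources) != 1:
            raise GraphStructureError(
                f"expected a unique source, found {len(sources)}: {sources!r}"
            )
        return sources[0]

    @property
    def sink(self) -> Node:
        _, sinks = self._degree_zero()
        if len(sinks) != 1:
            raise GraphStructureError(
                f"expected a unique sink, found {len(sinks)}: {sinks!r}"
            )
        return sinks[0]

    @property
    def total_flow(self) -> int:
        """|f|: the flow leaving the source."""
        s = self.source
        return sum(f for (u, _), f in self.flows.items() if u == s)

    @property
    def max_flow_value(self) -> int:
        return max(self.flows.values(), default=0)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), f in self.flows.items():
            g.add_edge(u, v, flow=f)
        return g


@dataclass
class IntervalFlowNetwork:
    """DAG whose edges carry an admissible interval [low, high] instead of a value."""

    graph_id: str
    nodes: list[Node]
    intervals: dict[Edge, tuple[int, int]]

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for (u, v), (lo, hi) in self.intervals.items():
            if u not in known or v not in known:
                raise GraphStructureError(f"edge ({u!r}, {v!r}) uses an unknown node")
            if lo < 0:
                raise ValueError(f"negative lower bound {lo} on edge ({u!r}, {v!r})")
            if hi < lo:
                raise ValueError(
                    f"interval [{lo}, {hi}] on edge ({u!r}, {v!r}) has high < low"
                )
        _check_dag(self.nodes, self.intervals)

    @property
    def edges(self) -> list[Edge]:
        return list(self.intervals)

    @property
    def source(self) -> Node:
        return self._as_network().source

    @property
    def sink(self) -> Node:
        return self._as_network().sink

    @property
    def max_high(self) -> int:
        return max((hi for _, hi in self.intervals.values()), default=0)

    def _as_network(self) -> FlowNetwork:
        return FlowNetwork(
            self.graph_id, list(self.nodes), {e: hi for e, (_, hi) in self.intervals.items()}
        )


@dataclass(frozen=True)
class Path:
    """A simple directed path given by its node sequence."""

    nodes: tuple[Node, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a path needs at least two nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path repeats a node")

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(zip(self.nodes, self.nodes[1:]))

    def __iter__(self):
        return iter(self.nodes)


@dataclass
class Decomposition:
    """A set of weighted source-to-sink paths.

    In ``integer`` weight mode all weights are positive integers; in ``real``
    mode weights are nonnegative floats and zero-weight paths are dropped
    before the object is reported.
    """

    paths: list[Path]
    weights: list[float]
    weight_domain: str = "integer"

    def __post_init__(self) -> None:
        if len(self.paths) != len(self.weights):
            raise ValueError("paths and weights differ in length")
        if self.weight_domain not in ("integer", "real"):
            raise ValueError(f"unknown weight domain {self.weight_domain!r}")
        if self.weight_domain == "integer":
            for w in self.weights:
                if int(w) != w or w < 1:
                    raise ValueError(f"integer-mode weight {w} is not a positive integer")
            self.weights = [int(w) for w in self.weights]
        else:
            kept = [(p, w) for p, w in zip(self.paths, self.weights) if w > 0]
            self.paths = [p for p, _ in kept]
            self.weights = [w for _, w in kept]

    @property
    def k(self) -> int:
        return len(self.paths)

    def superposition(self) -> dict[Edge, float]:
        sup: dict[Edge, float] = {}
        for p, w in zip(self.paths, self.weights):
            for e in p.edges:
                sup[e] = sup.get(e, 0) + w
        return sup


@dataclass
class Constraint:
    """Edges that must all be covered by a single decomposition path.

    A single leg is a classical subpath constraint (a long read); several
    edge-disjoint legs model paired-end or multi-end reads whose fragments
    must come from the same transcript.
    """

    constraint_id: str
    legs: list[list[Edge]]

    def __post_init__(self) -> None:
        if not self.legs or all(len(leg) == 0 for leg in self.legs):
            raise ValueError(f"constraint {self.constraint_id!r} has no edges")
        seen: set[Edge] = set()
        for leg in self.legs:
            for e in leg:
                if e in seen:
                    raise ValueError(
                        f"constraint {self.constraint_id!r}: legs share edge {e!r}"
                    )
                seen.add(e)

    @property
    def size(self) -> int:
        """Total number of edges across all legs (|R_j| in the model)."""
        return sum(len(leg) for leg in self.legs)

    @property
    def all_edges(self) -> list[Edge]:
        return [e for leg in self.legs for e in leg]


@dataclass
class ValidationReport:
    ok: bool
    edge_residuals: dict[Edge, float] = field(default_factory=dict)
    node_imbalance: dict[Node, float] = field(default_factory=dict)
    violated_constraints: list[str] = field(default_factory=list)


# -- operations ----------------------------------------------------------------


def ensure_single_source_sink(net: FlowNetwork) -> FlowNetwork:
    """Return ``net`` with a super-source/super-sink added if needed.

    Each original source gets one edge from the super-source carrying that
    node's total out-flow (symmetrically for sinks), so conservation status
    is preserved.  A network that already has a unique source and sink is
    returned unchanged (the same object).
    """
    sources, sinks = net._degree_zero()
    if not sources or not sinks:
        raise GraphStructureError("graph has no source-to-sink structure (empty?)")
    if len(sources) == 1 and len(sinks) == 1:
        return net
    nodes = list(net.nodes)
    flows = dict(net.flows)
    if len(sources) > 1:
        nodes.insert(0, SUPER_SOURCE)
        for n in sources:
            out = sum(f for (u, _), f in net.flows.items() if u == n)
            flows[(SUPER_SOURCE, n)] = out
    if len(sinks) > 1:
        nodes.append(SUPER_SINK)
        for n in sinks:
            inn = sum(f for (_, v), f in net.flows.items() if v == n)
            flows[(n, SUPER_SINK)] = inn
    return FlowNetwork(net.graph_id, nodes, flows, conserving=net.conserving)


def strip_super_nodes(dec: Decomposition) -> Decomposition:
    """Remove normalization-added super source/sink from reported paths."""
    out = []
    for p in dec.paths:
        nodes = tuple(n for n in p.nodes if n not in (SUPER_SOURCE, SUPER_SINK))
        out.append(Path(nodes))
    return Decomposition(out, list(dec.weights), dec.weight_domain)


def check_flow_conservation(net: FlowNetwork) -> ValidationReport:
    """Check Kirchhoff balance (inflow == outflow) at every internal node."""
    s, t = net.source, net.sink
    imbalance: dict[Node, float] = {}
    for v in net.nodes:
        if v in (s, t):
            continue
        inflow = sum(f for (a, b), f in net.flows.items() if b == v)
        outflow = sum(f for (a, b), f in net.flows.items() if a == v)
        imbalance[v] = inflow - outflow
    ok = all(x == 0 for x in imbalance.values())
    net.conserving = ok
    return ValidationReport(ok=ok, node_imbalance=imbalance)


def _check_paths_structural(net, dec: Decomposition, edges: set[Edge]) -> None:
    s = net.source
    t = net.sink
    for p in dec.paths:
        if p.nodes[0] != s or p.nodes[-1] != t:
            raise GraphStructureError(
                f"path {'-'.join(p.nodes)} is not a source-to-sink path"
            )
        for e in p.edges:
            if e not in edges:
                raise GraphStructureError(
                    f"path {'-'.join(p.nodes)} uses missing edge {e!r}"
                )


def validate_decomposition(
    net: FlowNetwork,
    dec: Decomposition,
    mode: str = "exact",
    interval_net: Optional[IntervalFlowNetwork] = None,
) -> ValidationReport:
    """Check that the weighted-path superposition reproduces the edge values.

    ``exact`` mode requires equality with ``net``'s flow on every edge;
    ``interval`` mode requires the superposition to lie within the given
    ``interval_net`` bounds.
    """
    if mode == "interval":
        if interval_net is None:
            raise ValueError("interval mode requires interval_net")
        edges = set(interval_net.intervals)
        _check_paths_structural(interval_net, dec, edges)
        sup = dec.superposition()
        residuals: dict[Edge, float] = {}
        ok = True
        for e, (lo, hi) in interval_net.intervals.items():
            x = sup.get(e, 0)
            if x < lo:
                residuals[e] = x - lo
                ok = False
            elif x > hi:
                residuals[e] = x - hi
                ok = False
            else:
                residuals[e] = 0
        return ValidationReport(ok=ok, edge_residuals=residuals)

    edges = set(net.flows)
    _check_paths_structural(net, dec, edges)
    sup = dec.superposition()
    residuals = {e: sup.get(e, 0) - f for e, f in net.flows.items()}
    for e in sup:
        if e not in residuals:  # cannot happen after the structural check
            residuals[e] = sup[e]
    ok = all(r == 0 for r in residuals.values())
    return ValidationReport(ok=ok, edge_residuals=residuals)


def validate_constraints(dec: Decomposition, constraints: Sequence[Constraint],
                         net: Optional[FlowNetwork] = None) -> ValidationReport:
    """Check that every constraint's edges are covered by one path of ``dec``.

    For a single-leg constraint this is exactly subpath containment: a simple
    path containing all edges of another path contains them consecutively.
    """
    if net is not None:
        edges = set(net.flows)
        for c in constraints:
            for e in c.all_edges:
                if e not in edges:
                    raise GraphStructureError(
                        f"constraint {c.constraint_id!r} references missing edge {e!r}"
                    )
    violated = []
    path_edge_sets = [set(p.edges) for p in dec.paths]
    for c in constraints:
        need = set(c.all_edges)
        if not any(need <= pes for pes in path_edge_sets):
            violated.append(c.constraint_id)
    return ValidationReport(ok=not violated, violated_constraints=violated)


def lower_bound_k(net: FlowNetwork) -> int:
    """Degree lower bound on the size of any decomposition.

    Every positive-flow edge must be covered and a single path uses at most
    one in-edge and one out-edge per node, so no decomposition can be smaller
    than the largest in- or out-degree over positive-flow edges.
    """
    best = 0
    for v in net.nodes:
        indeg = sum(1 for (a, b), f in net.flows.items() if b == v and f > 0)
        outdeg = sum(1 for (a, b), f in net.flows.items() if a == v and f > 0)
        best = max(best, indeg, outdeg)
    return max(best, 1)


def unit_decomposition(net: FlowNetwork) -> Decomposition:
    """The |f|-path, weight-one decomposition of a conserving network.

    Repeatedly traces a positive-residual source-to-sink path and removes one
    unit of flow along it.  Exists for any conserving network with integer
    flows; used as a constructive feasibility witness and upper bound.
    """
    if net.conserving is None:
        check_flow_conservation(net)
    if not net.conserving:
        raise ValueError("unit decomposition requires a conserving network")
    residual = dict(net.flows)
    s, t = net.source, net.sink
    out_adj: dict[Node, list[Edge]] = {}
    for e in net.flows:
        out_adj.setdefault(e[0], []).append(e)
    paths = []
    while True:
        if all(residual[e] == 0 for e in out_adj.get(s, [])):
            break
        nodes = [s]
        while nodes[-1] != t:
            nxt = next(e for e in out_adj[nodes[-1]] if residual[e] > 0)
            residual[nxt] -= 1
            nodes.append(nxt[1])
        paths.append(Path(tuple(nodes)))
    return Decomposition(paths, [1] * len(paths), "integer")
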