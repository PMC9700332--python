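"""Text I/O for flow-network instances, constraints and decompositions.

The graph dialect follows the edge-list files used by the common flow
decomposition benchmark collections: each graph is one block

    # <free text used as graph id>
    <number of vertices>
    <tail> <head> <flow>          (exact dialect)
    <tail> <head> <low> <high>    (interval dialect)

Constraints files use the same per-graph ``#`` headers followed by one
constraint per line: a space-separated node sequence, with ``;`` separating
the legs of a generalized (paired-end / multi-end) constraint.
"""

from __future__ import annotations

import json
from typing import Iterable, List, Sequence, TextIO, Union

from .network import (
    Constraint,
    Decomposition,
    FlowNetwork,
    IntervalFlowNetwork,
)

__all__ = [
    "GraphFormatError",
    "read_graph_file",
    "write_graph_file",
    "read_constraints_file",
    "write_constraints_file",
    "decomposition_to_json",
    "decomposition_to_tsv",
]

AnyNetwork = Union[FlowNetwork, IntervalFlowNetwork]


class GraphFormatError(ValueError):
    """Malformed instance file; message carries the 1-based line number."""


def _finish_block(graph_id, n_declared, edge_rows, dialect, keep_zero_edges, lineno):
    nodes: list[str] = []
    seen = set()

    def _add(n):
        if n not in seen:
            seen.add(n)
            nodes.append(n)

    if dialect == "exact":
        flows = {}
        for (u, v, vals, ln) in edge_rows:
            (f,) = vals
            if f < 0:
                raise ValueError(f"line {ln}: negative flow {f}")
            if (u, v) in flows:
                raise GraphFormatError(f"line {ln}: duplicate edge {u} {v}")
            if f == 0 and not keep_zero_edges:
                continue
            flows[(u, v)] = f
            _add(u)
            _add(v)
        net: AnyNetwork = FlowNetwork(graph_id, nodes, flows)
    else:
        intervals = {}
        for (u, v, vals, ln) in edge_rows:
            lo, hi = vals
            if lo < 0:
                raise ValueError(f"line {ln}: negative lower bound {lo}")
            if hi < lo:
                raise ValueError(f"line {ln}: interval [{lo}, {hi}] has high < low")
            if (u, v) in intervals:
                raise GraphFormatError(f"line {ln}: duplicate edge {u} {v}")
            intervals[(u, v)] = (lo, hi)
            _add(u)
            _add(v)
        net = IntervalFlowNetwork(graph_id, nodes, intervals)
    # the vertex-count line is validated loosely: ids need not be 0..n-1
    if n_declared is not None and edge_rows and len(seen) > n_declared:
        raise GraphFormatError(
            f"graph {graph_id!r}: {len(seen)} distinct node ids exceed the "
            f"declared vertex count {n_declared}"
        )
    return net


def read_graph_file(
    stream: TextIO, dialect: str = "exact", keep_zero_edges: bool = False
) -> List[AnyNetwork]:
    """Parse all graph blocks from ``stream``; one network per ``#`` header.

    Zero-flow edges are dropped by default (a positive decomposition cannot
    use them); pass ``keep_zero_edges=True`` to retain them.
    """
    if dialect not in ("exact", "interval"):
        raise ValueError(f"unknown dialect {dialect!r}")
    n_vals = 1 if dialect == "exact" else 2
    nets: list[AnyNetwork] = []
    graph_id = None
    n_declared = None
    edge_rows: list = []
    start_line = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if graph_id is not None:
                nets.append(
                    _finish_block(graph_id, n_declared, edge_rows, dialect,
                                  keep_zero_edges, start_line)
                )
            graph_id = line.lstrip("#").strip() or f"graph-{len(nets)}"
            n_declared = None
            edge_rows = []
            start_line = lineno
            continue
        if graph_id is None:
            raise GraphFormatError(f"line {lineno}: data before the first '#' header")
        parts = line.split()
        if n_declared is None:
            if len(parts) != 1:
                raise GraphFormatError(
                    f"line {lineno}: expected the vertex-count line, got {line!r}"
                )
            try:
                n_declared = int(parts[0])
            except ValueError as exc:
                raise GraphFormatError(f"line {lineno}: bad vertex count {line!r}") from exc
            continue
        if len(parts) != 2 + n_vals:
            raise GraphFormatError(
                f"line {lineno}: expected 'tail head "
                + ("flow'" if dialect == "exact" else "low high'")
                + f", got {line!r}"
            )
        try:
            vals = tuple(int(p) for p in parts[2:])
        except ValueError as exc:
            raise GraphFormatError(f"line {lineno}: non-integer value in {line!r}") from exc
        edge_rows.append((parts[0], parts[1], vals, lineno))
    if graph_id is not None:
        nets.append(
            _finish_block(graph_id, n_declared, edge_rows, dialect,
                          keep_zero_edges, start_line)
        )
    return nets


def write_graph_file(networks: Sequence[AnyNetwork], stream: TextIO,
                     dialect: str = "exact") -> None:
    for net in networks:
        stream.write(f"# {net.graph_id}\n")
        stream.write(f"{len(net.nodes)}\n")
        if dialect == "exact":
            for (u, v), f in net.flows.items():
                stream.write(f"{u} {v} {f}\n")
        elif dialect == "interval":
            for (u, v), (lo, hi) in net.intervals.items():
                stream.write(f"{u} {v} {lo} {hi}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_constraints_file(stream: TextIO) -> dict[str, list[Constraint]]:
    """Parse per-graph constraint blocks into node-sequence constraints.

    Returns a map graph_id -> constraints.  Each non-header line is one
    constraint; ``;`` separates the legs of a generalized constraint.
    """
    out: dict[str, list[Constraint]] = {}
    graph_id = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            graph_id = line.lstrip("#").strip()
            out.setdefault(graph_id, [])
            continue
        if graph_id is None:
            raise GraphFormatError(f"line {lineno}: constraint before any '#' header")
        legs = []
        for leg_text in line.split(";"):
            nodes = leg_text.split()
            if len(nodes) < 2:
                raise GraphFormatError(
                    f"line {lineno}: a constraint leg needs at least two nodes"
                )
            legs.append(list(zip(nodes, nodes[1:])))
        cid = f"{graph_id}:c{len(out[graph_id])}"
        out[graph_id].append(Constraint(cid, legs))
    return out


def write_constraints_file(per_graph: dict[str, Sequence[Constraint]],
                           stream: TextIO) -> None:
    for graph_id, constraints in per_graph.items():
        stream.write(f"# {graph_id}\n")
        for c in constraints:
            legs_text = []
            for leg in c.legs:
                nodes = [leg[0][0]] + [e[1] for e in leg]
                legs_text.append(" ".join(nodes))
            stream.write(" ; ".join(legs_text) + "\n")


def decomposition_to_json(graph_id: str, dec: Decomposition | None,
                          status: str, k: int | None = None,
                          objective: float | None = None) -> str:
    payload = {
        "graph_id": graph_id,
        "k": k if k is not None else (dec.k if dec is not None else None),
        "paths": [list(p.nodes) for p in dec.paths] if dec is not None else [],
        "weights": list(dec.weights) if dec is not None else [],
        "status": status,
    }
    if objective is not None:
        payload["objective"] = objective
    return json.dumps(payload, indent=2)


def decomposition_to_tsv(dec: Decomposition) -> str:
    lines = []
    for p, w in zip(dec.paths, dec.weights):
        lines.append(f"{w}\t{','.join(p.nodes)}")
    return "\n".join(lines) + ("\n" if lines else "")
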