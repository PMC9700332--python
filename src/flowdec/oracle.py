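"""Brute-force reference solver for tiny instances.

Exhaustive ground truth used to verify the MILP solvers: enumerate all simple
source-to-sink paths, then search subsets of paths and integer weight vectors
directly.  Deliberately exponential; hard caps raise errors instead of
truncating the search, so the oracle is never approximate.

Weight search spaces (sound by construction):

* exact mode — weights of a decomposition must sum to |f| (the flow leaving
  the source), so weight vectors are the compositions of |f| into k positive
  parts, pruned edge-wise against the flow;
* interval mode — any weight exceeds no edge interval's upper bound, so each
  weight ranges over 1..max_high;
* bounded mode — a weight above max_f + B forces error > B on every edge of
  its path, so each weight ranges over 1..max_f + B;
* min-error mode — reducing a weight above max_f strictly reduces every
  deviation it causes, so each weight ranges over 1..max_f.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .network import (
    Constraint,
    Decomposition,
    Edge,
    FlowNetwork,
    IntervalFlowNetwork,
    Path,
    lower_bound_k,
)

__all__ = [
    "OracleSizeError",
    "OracleResult",
    "enumerate_st_paths",
    "oracle_min_k",
    "oracle_min_error_at_k",
]

MAX_PATHS = 10_000
MAX_TOTAL_FLOW = 2_000


class OracleSizeError(ValueError):
    """Instance exceeds the oracle's hard size caps."""


@dataclass
class OracleResult:
    min_k: Optional[int]
    objective: Optional[float]
    witness: Optional[Decomposition]


def enumerate_st_paths(net: FlowNetwork | IntervalFlowNetwork,
                       cap: int = MAX_PATHS) -> list[Path]:
    """All simple s-t paths, in lexicographic node-sequence order."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    s = net.source
    t = net.sink
    out: list[Path] = []
    for nodes in nx.all_simple_paths(g, s, t):
        out.append(Path(tuple(nodes)))
        if len(out) > cap:
            raise OracleSizeError(f"more than {cap} s-t paths")
    out.sort(key=lambda p: p.nodes)
    return out


def _subset_satisfies(paths: Sequence[Path],
                      constraints: Sequence[Constraint]) -> bool:
    sets = [set(p.edges) for p in paths]
    return all(any(set(c.all_edges) <= s for s in sets) for c in constraints)


def _edge_index(subset: Sequence[Path]):
    """Per-edge list of using-path positions and the last position using it."""
    users: dict[Edge, list[int]] = {}
    for i, p in enumerate(subset):
        for e in p.edges:
            users.setdefault(e, []).append(i)
    last = {e: idx[-1] for e, idx in users.items()}
    return users, last


def _search_exact(subset, flows, total):
    """Compositions of ``total`` into positive weights, pruned edge-wise."""
    k = len(subset)
    _, last = _edge_index(subset)
    sup: dict[Edge, int] = {e: 0 for e in last}
    finish_at: dict[int, list[Edge]] = {}
    for e, i in last.items():
        finish_at.setdefault(i, []).append(e)
    weights = [0] * k

    def rec(i: int, remaining: int):
        if i == k - 1:
            candidates = [remaining]
        else:
            candidates = range(1, remaining - (k - 1 - i) + 1)
        for w in candidates:
            ok = True
            touched = subset[i].edges
            for e in touched:
                sup[e] += w
                if sup[e] > flows[e]:
                    ok = False
            if ok:
                for e in finish_at.get(i, []):
                    if sup[e] != flows[e]:
                        ok = False
                        break
            if ok:
                weights[i] = w
                if i == k - 1:
                    yield list(weights)
                else:
                    yield from rec(i + 1, remaining - w)
            for e in touched:
                sup[e] -= w

    yield from rec(0, total)


def _search_interval(subset, intervals, wbar):
    k = len(subset)
    _, last = _edge_index(subset)
    sup: dict[Edge, int] = {e: 0 for e in last}
    finish_at: dict[int, list[Edge]] = {}
    for e, i in last.items():
        finish_at.setdefault(i, []).append(e)
    weights = [0] * k

    def rec(i: int):
        for w in range(1, wbar + 1):
            ok = True
            touched = subset[i].edges
            for e in touched:
                sup[e] += w
                if sup[e] > intervals[e][1]:
                    ok = False
            if ok:
                for e in finish_at.get(i, []):
                    if sup[e] < intervals[e][0]:
                        ok = False
                        break
            if ok:
                weights[i] = w
                if i == k - 1:
                    yield list(weights)
                else:
                    yield from rec(i + 1)
            for e in touched:
                sup[e] -= w

    yield from rec(0)


def _search_bounded(subset, flows, B, wbar):
    k = len(subset)
    users, last = _edge_index(subset)
    base_err = sum(f for e, f in flows.items() if e not in users)
    if base_err > B:
        return
    sup: dict[Edge, int] = {e: 0 for e in last}
    finish_at: dict[int, list[Edge]] = {}
    for e, i in last.items():
        finish_at.setdefault(i, []).append(e)
    weights = [0] * k

    def rec(i: int, err: int):
        for w in range(1, wbar + 1):
            touched = subset[i].edges
            for e in touched:
                sup[e] += w
            new_err = err
            ok = True
            for e in touched:  # overshoot on open edges only grows
                if sup[e] - flows[e] > 0 and last[e] != i:
                    if err + (sup[e] - flows[e]) > B:
                        ok = False
                        break
            if ok:
                for e in finish_at.get(i, []):
                    new_err += abs(sup[e] - flows[e])
                    if new_err > B:
                        ok = False
                        break
            if ok:
                weights[i] = w
                if i == k - 1:
                    yield list(weights), new_err
                else:
                    yield from rec(i + 1, new_err)
            for e in touched:
                sup[e] -= w

    yield from rec(0, base_err)


def _search_min_sq(subset, flows, wbar, best_bound):
    """Minimum total squared deviation over weight vectors; None if >= bound."""
    k = len(subset)
    users, last = _edge_index(subset)
    base = sum(f * f for e, f in flows.items() if e not in users)
    best: Optional[tuple[float, list[int]]] = None
    limit = best_bound
    if base >= limit:
        return None
    sup: dict[Edge, int] = {e: 0 for e in last}
    finish_at: dict[int, list[Edge]] = {}
    for e, i in last.items():
        finish_at.setdefault(i, []).append(e)
    weights = [0] * k

    def rec(i: int, err: float):
        nonlocal best, limit
        for w in range(1, wbar + 1):
            touched = subset[i].edges
            for e in touched:
                sup[e] += w
            new_err = err
            ok = True
            for e in finish_at.get(i, []):
                new_err += (sup[e] - flows[e]) ** 2
                if new_err >= limit:
                    ok = False
                    break
            if ok:
                for e in touched:
                    if last[e] != i and sup[e] > flows[e]:
                        if new_err + (sup[e] - flows[e]) ** 2 >= limit:
                            ok = False
                            break
            if ok:
                if i == k - 1:
                    if new_err < limit:
                        weights[i] = w
                        best = (new_err, list(weights))
                        limit = new_err
                else:
                    weights[i] = w
                    rec(i + 1, new_err)
            for e in touched:
                sup[e] -= w

    rec(0, base)
    return best


def _check_caps(net, paths):
    if isinstance(net, FlowNetwork):
        total = net.total_flow
        if total > MAX_TOTAL_FLOW:
            raise OracleSizeError(f"total flow {total} exceeds cap {MAX_TOTAL_FLOW}")


def oracle_min_k(net: FlowNetwork | IntervalFlowNetwork,
                 constraints: Optional[Sequence[Constraint]] = None,
                 mode: str = "exact",
                 B: Optional[int] = None,
                 max_k: Optional[int] = None) -> OracleResult:
    """Exhaustive minimum-k search (modes: exact, interval, bounded, minerr).

    Returns the minimum k meeting the mode's criterion, the best objective
    (min-error mode only) and one witness decomposition.  ``min_k`` is None
    when no k within the scan bound is feasible (possible for constrained or
    bounded-error instances).
    """
    constraints = list(constraints or [])
    paths = enumerate_st_paths(net)
    _check_caps(net, paths)
    m = len(net.edges)

    if mode == "exact":
        assert isinstance(net, FlowNetwork)
        flows = net.flows
        total = net.total_flow
        kmax = max_k if max_k is not None else min(m, total)
        kmin = lower_bound_k(net)
        for k in range(kmin, kmax + 1):
            for subset in itertools.combinations(paths, k):
                covered = set().union(*(set(p.edges) for p in subset))
                if covered != set(flows):
                    continue
                if constraints and not _subset_satisfies(subset, constraints):
                    continue
                for weights in _search_exact(list(subset), flows, total):
                    dec = Decomposition(list(subset), weights, "integer")
                    return OracleResult(k, None, dec)
        return OracleResult(None, None, None)

    if mode == "interval":
        assert isinstance(net, IntervalFlowNetwork)
        intervals = net.intervals
        wbar = net.max_high
        kmax = max_k if max_k is not None else m
        must_cover = {e for e, (lo, _) in intervals.items() if lo > 0}
        for k in range(1, kmax + 1):
            for subset in itertools.combinations(paths, k):
                covered = set().union(*(set(p.edges) for p in subset))
                if not must_cover <= covered:
                    continue
                if constraints and not _subset_satisfies(subset, constraints):
                    continue
                for weights in _search_interval(list(subset), intervals, wbar):
                    dec = Decomposition(list(subset), weights, "integer")
                    return OracleResult(k, None, dec)
        return OracleResult(None, None, None)

    if mode == "bounded":
        assert isinstance(net, FlowNetwork)
        if B is None or B < 0:
            raise ValueError("bounded mode requires B >= 0")
        flows = net.flows
        wbar = net.max_flow_value + B
        kmax = max_k if max_k is not None else m
        for k in range(1, kmax + 1):
            for subset in itertools.combinations(paths, k):
                if constraints and not _subset_satisfies(subset, constraints):
                    continue
                for weights, err in _search_bounded(list(subset), flows, B, wbar):
                    dec = Decomposition(list(subset), weights, "integer")
                    return OracleResult(k, float(err), dec)
        return OracleResult(None, None, None)

    if mode == "minerr":
        assert isinstance(net, FlowNetwork)
        kmax = max_k if max_k is not None else m
        best_obj = float("inf")
        best_k = None
        best_witness = None
        for k in range(1, kmax + 1):
            res = oracle_min_error_at_k(net, k, best_bound=best_obj)
            if res is not None and res[0] < best_obj:
                best_obj, best_witness = res[0], res[1]
                best_k = k
            if best_obj == 0:
                break
        if best_k is None:
            return OracleResult(None, None, None)
        return OracleResult(best_k, best_obj, best_witness)

    raise ValueError(f"unknown oracle mode {mode!r}")


def oracle_min_error_at_k(net: FlowNetwork, k: int,
                          distinct: bool = True,
                          best_bound: float = float("inf")
                          ) -> Optional[tuple[float, Decomposition]]:
    """Minimum total squared error achievable with exactly k weighted paths.

    With ``distinct=False`` path multisets are searched, matching a solver
    that may assign two path indices the same edge set.  Returns None when
    nothing beats ``best_bound``.
    """
    paths = enumerate_st_paths(net)
    _check_caps(net, paths)
    flows = net.flows
    wbar = max(net.max_flow_value, 1)
    combos = (itertools.combinations(paths, k) if distinct
              else itertools.combinations_with_replacement(paths, k))
    best: Optional[tuple[float, Decomposition]] = None
    bound = best_bound
    for subset in combos:
        res = _search_min_sq(list(subset), flows, wbar, bound)
        if res is not None:
            obj, weights = res
            best = (float(obj), Decomposition(list(subset), weights, "integer"))
            bound = obj
            if obj == 0:
                break
    return best
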