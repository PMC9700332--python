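"""Minimal-k drivers for every decomposition problem, plus optima enumeration.

Each driver scans k upward, solving one fixed-k MILP per value, and returns
the first feasible k with its decomposition.  The scan is sound because
feasibility is monotone in k for every variant (a path of weight > 1 can be
split in two); it starts at the degree lower bound where one applies and
stops at a problem-specific upper bound:

* exact MFD:      min(|E|, |f|)  — any integer decomposition has <= |f| paths
                  of weight >= 1 and any flow decomposes into <= |E| paths;
* with subpath constraints: |f|;
* interval / imperfect: |E| — any weighted path set induces a flow,
  decomposable into <= |E| paths.

A binary-search scan is available for the plain problems where feasibility
monotonicity in k holds instance-independently.  One wall-clock budget is
shared across the whole scan.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ilp import (
    KfdModel,
    SolveOutcome,
    SolverConfig,
    build_kfd_model,
    extract_decomposition,
    solve_model,
)
from .network import (
    Constraint,
    Decomposition,
    FlowNetwork,
    IntervalFlowNetwork,
    check_flow_conservation,
    ensure_single_source_sink,
    lower_bound_k,
    strip_super_nodes,
)
from .variants import (
    add_path_constraints,
    build_bounded_error_model,
    build_inexact_model,
    build_min_error_model,
)

__all__ = [
    "MfdResult",
    "solve_mfd",
    "solve_mfd_subpath",
    "solve_mifd",
    "solve_imperfect_bounded",
    "solve_imperfect_minerr",
    "enumerate_optimal_decompositions",
]


@dataclass
class MfdResult:
    graph_id: str
    problem: str
    min_k: Optional[int] = None
    decomposition: Optional[Decomposition] = None
    objective: Optional[float] = None
    per_k_log: list[tuple[int, str, float]] = field(default_factory=list)
    status: str = "solved"


class _Budget:
    def __init__(self, seconds: float):
        self.deadline = time.monotonic() + seconds

    @property
    def remaining(self) -> float:
        return self.deadline - time.monotonic()

    @property
    def exhausted(self) -> bool:
        return self.remaining <= 0


def _scan(graph_id: str, problem: str, build, k_lo: int, k_hi: int,
          config: SolverConfig, binary_search: bool = False) -> MfdResult:
    """Find the smallest feasible k in [k_lo, k_hi] for ``build(k)`` models."""
    result = MfdResult(graph_id=graph_id, problem=problem)
    budget = _Budget(config.time_limit)

    def attempt(k: int) -> tuple[str, Optional[Decomposition]]:
        if budget.exhausted:
            return "time_limit", None
        model = build(k)
        sub = SolverConfig(**{**config.__dict__, "time_limit": max(budget.remaining, 0.01)})
        outcome = solve_model(model, sub)
        result.per_k_log.append((k, outcome.status, outcome.wall_time))
        if outcome.status in ("optimal", "feasible"):
            dec = strip_super_nodes(extract_decomposition(model, outcome))
            return "feasible", dec
        return outcome.status, None

    if not binary_search:
        for k in range(k_lo, k_hi + 1):
            status, dec = attempt(k)
            if status == "feasible":
                result.min_k, result.decomposition = k, dec
                return result
            if status == "time_limit":
                result.status = "time_limit"
                return result
        result.status = "infeasible"
        return result

    lo, hi = k_lo, k_hi
    best: Optional[tuple[int, Decomposition]] = None
    while lo <= hi:
        mid = (lo + hi) // 2
        status, dec = attempt(mid)
        if status == "feasible":
            best = (mid, dec)
            hi = mid - 1
        elif status == "time_limit":
            result.status = "time_limit"
            return result
        else:
            lo = mid + 1
    if best is None:
        result.status = "infeasible"
    else:
        result.min_k, result.decomposition = best
    return result


def _prepare_exact(net: FlowNetwork, problem: str) -> FlowNetwork:
    net = ensure_single_source_sink(net)
    if net.conserving is None:
        check_flow_conservation(net)
    if not net.conserving:
        raise ValueError(
            f"{problem}: edge values do not conserve flow; use "
            "solve_imperfect_bounded or solve_imperfect_minerr"
        )
    return net


def solve_mfd(net: FlowNetwork, config: Optional[SolverConfig] = None,
              scan_from_one: bool = False, binary_search: bool = False) -> MfdResult:
    """Minimum flow decomposition of a conserving network."""
    config = config or SolverConfig()
    net = _prepare_exact(net, "MFD")
    k_lo = 1 if scan_from_one else lower_bound_k(net)
    k_hi = min(len(net.edges), net.total_flow)
    return _scan(net.graph_id, "mfd", lambda k: build_kfd_model(net, k, config),
                 k_lo, k_hi, config, binary_search)


def solve_mfd_subpath(net: FlowNetwork, constraints: Sequence[Constraint],
                      config: Optional[SolverConfig] = None,
                      scan_from_one: bool = False) -> MfdResult:
    """Minimum decomposition whose paths cover every given constraint."""
    config = config or SolverConfig()
    if not constraints:
        res = solve_mfd(net, config, scan_from_one=scan_from_one)
        res.problem = "mfdsc"
        return res
    net = _prepare_exact(net, "MFDSC")

    def build(k: int) -> KfdModel:
        return add_path_constraints(build_kfd_model(net, k, config), constraints)

    k_lo = 1 if scan_from_one else lower_bound_k(net)
    k_hi = net.total_flow  # any integer decomposition has at most |f| paths
    return _scan(net.graph_id, "mfdsc", build, k_lo, k_hi, config)


def _interval_lower_bound(net: IntervalFlowNetwork) -> int:
    best = 1
    for v in net.nodes:
        indeg = sum(1 for (a, b), (lo, _) in net.intervals.items()
                    if b == v and lo > 0)
        outdeg = sum(1 for (a, b), (lo, _) in net.intervals.items()
                     if a == v and lo > 0)
        best = max(best, indeg, outdeg)
    return best


def solve_mifd(interval_net: IntervalFlowNetwork,
               config: Optional[SolverConfig] = None,
               binary_search: bool = False) -> MfdResult:
    """Minimum inexact decomposition: superposition within every interval."""
    config = config or SolverConfig()
    if not interval_net.edges:
        raise ValueError("interval network has no edges")
    k_lo = _interval_lower_bound(interval_net)
    k_hi = len(interval_net.edges)
    return _scan(interval_net.graph_id, "mifd",
                 lambda k: build_inexact_model(interval_net, k, config),
                 k_lo, k_hi, config, binary_search)


def solve_imperfect_bounded(net: FlowNetwork, B: int,
                            config: Optional[SolverConfig] = None) -> MfdResult:
    """Minimum path set whose total absolute flow error is at most B."""
    config = config or SolverConfig()
    net = ensure_single_source_sink(net)
    return _scan(net.graph_id, "imperfect_bounded",
                 lambda k: build_bounded_error_model(net, k, B, config),
                 1, len(net.edges), config)


def solve_imperfect_minerr(net: FlowNetwork,
                           config: Optional[SolverConfig] = None,
                           max_k: Optional[int] = None) -> MfdResult:
    """Smallest k attaining the minimum total squared flow error.

    Computes the per-k optimum E_k for k = 1..max_k and returns the smallest
    k with E_k equal to the overall minimum (E_k need not be monotone under
    integer weights, so the whole range is scanned unless E_k hits 0).
    """
    config = config or SolverConfig()
    net = ensure_single_source_sink(net)
    k_hi = max_k if max_k is not None else len(net.edges)
    budget = _Budget(config.time_limit)
    result = MfdResult(graph_id=net.graph_id, problem="imperfect_minerr")
    best: Optional[tuple[float, int, Decomposition]] = None
    for k in range(1, k_hi + 1):
        if budget.exhausted:
            result.status = "time_limit"
            return result
        model = build_min_error_model(net, k, config)
        sub = SolverConfig(**{**config.__dict__, "time_limit": max(budget.remaining, 0.01)})
        outcome = solve_model(model, sub)
        result.per_k_log.append((k, outcome.status, outcome.wall_time))
        if outcome.status == "time_limit":
            result.status = "time_limit"
            return result
        if outcome.status not in ("optimal", "feasible"):
            continue
        obj = round(outcome.objective_value, 6) if outcome.objective_value else 0.0
        if best is None or obj < best[0]:
            dec = strip_super_nodes(extract_decomposition(model, outcome))
            best = (obj, k, dec)
        if best[0] == 0:
            break
    if best is None:
        result.status = "infeasible"
        return result
    result.objective, result.min_k, result.decomposition = best
    return result


def enumerate_optimal_decompositions(net: FlowNetwork, k: int, limit: int,
                                     config: Optional[SolverConfig] = None
                                     ) -> list[Decomposition]:
    """Distinct k-path decompositions via iterated no-good cuts.

    Re-solves the k-FD model, each time excluding the previous binary
    edge-use assignment; results equal as multisets of (path, weight) pairs
    are deduplicated (path-index permutations are model symmetries).
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    config = config or SolverConfig()
    net = _prepare_exact(net, "enumerate")
    model = build_kfd_model(net, k, config)
    found: list[Decomposition] = []
    seen: set = set()
    budget = _Budget(config.time_limit)
    while len(found) < limit and not budget.exhausted:
        sub = SolverConfig(**{**config.__dict__, "time_limit": max(budget.remaining, 0.01)})
        outcome = solve_model(model, sub)
        if outcome.status not in ("optimal", "feasible"):
            break
        dec = strip_super_nodes(extract_decomposition(model, outcome))
        key = frozenset(
            ((p.nodes, w), sum(1 for q, u in zip(dec.paths, dec.weights)
                               if q.nodes == p.nodes and u == w))
            for p, w in zip(dec.paths, dec.weights)
        )
        if key not in seen:
            seen.add(key)
            found.append(dec)
        # no-good cut on the current x-assignment
        ones = [j for (e, i), j in model.x.items()
                if outcome.assignment[j] >= 0.5]
        zeros = [j for (e, i), j in model.x.items()
                 if outcome.assignment[j] < 0.5]
        coeffs = {j: -1.0 for j in ones}
        for j in zeros:
            coeffs[j] = 1.0
        model.lp.add_row(coeffs, 1.0 - len(ones), float("inf"))
    return found
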