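"""The k-flow-decomposition MILP: path encoding, superposition, linearization.

A k-FD asks for k source-to-sink paths with positive weights whose edge-wise
weight superposition equals the given flow.  All exponentially many s-t paths
of the DAG are represented implicitly: per path index i, binary edge-use
variables x_uvi are constrained to carry a unit of "conceptual" flow from s
to t, which in a DAG characterizes exactly the simple s-t paths.  The
nonlinear superposition condition

    sum_i x_uvi * w_i = f_uv        for every edge (u, v)

is linearized with product variables pi_uvi and a big-M constant w_bar
(an upper bound on any path weight, by default the largest edge value):

    pi_uvi <= w_bar * x_uvi
    pi_uvi <= w_i
    pi_uvi >= w_i - (1 - x_uvi) * w_bar

so pi_uvi = x_uvi * w_i in every feasible assignment.  The model has
Theta(k * |E|) variables and constraints.  Integer weight mode requires
w_i >= 1; real mode relaxes the weights to continuous >= 0 (zero-weight
paths are dropped on extraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .milp import BackendError, LinearProgram, LpSolution
from .network import (
    Decomposition,
    Edge,
    FlowNetwork,
    IntervalFlowNetwork,
    Path,
    check_flow_conservation,
)

__all__ = [
    "SolverConfig",
    "KfdModel",
    "SolveOutcome",
    "ExtractionError",
    "build_kfd_model",
    "solve_model",
    "extract_decomposition",
]


@dataclass
class SolverConfig:
    """Solver and model options shared by all problem variants.

    ``weight_upper_bound`` overrides the big-M constant w_bar; it must be at
    least the largest edge value or the model would cut off valid weights.
    ``symmetry_breaking`` adds w_1 <= ... <= w_k, which removes the
    path-index permutation symmetry without changing feasibility.
    """

    backend: str = "highs"
    time_limit: float = 60.0
    weight_domain: str = "integer"
    weight_upper_bound: Optional[int] = None
    symmetry_breaking: bool = False
    threads: int = 1
    solver_seed: Optional[int] = None
    real_weight_floor: float = 1.0  # weight floor used when constraints + real mode
    mip_rel_gap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time_limit <= 0:
            raise ValueError("time_limit must be positive")
        if self.weight_domain not in ("integer", "real"):
            raise ValueError(f"unknown weight domain {self.weight_domain!r}")
        if self.backend != "highs":
            raise BackendError(f"solver backend {self.backend!r} is not available")


@dataclass
class KfdModel:
    """Container tying the LP variables back to the network structure."""

    net: FlowNetwork | IntervalFlowNetwork
    k: int
    lp: LinearProgram
    wbar: float
    weight_domain: str
    x: dict[tuple[Edge, int], int] = field(default_factory=dict)
    w: dict[int, int] = field(default_factory=dict)
    pi: dict[tuple[Edge, int], int] = field(default_factory=dict)
    r: dict[tuple[int, str], int] = field(default_factory=dict)
    err: dict[Edge, int] = field(default_factory=dict)
    objective_kind: str = "feasibility"
    _real_floor: float = 1.0  # weight floor applied when constraints meet real mode


@dataclass
class SolveOutcome:
    status: str  # optimal | feasible | infeasible | time_limit | error
    assignment: Optional[dict[int, float]]
    objective_value: Optional[float]
    wall_time: float


class ExtractionError(RuntimeError):
    """The solver's x-assignment does not form unit s-t paths (tolerance pathology)."""


def _add_path_encoding(lp: LinearProgram, net, k: int) -> dict[tuple[Edge, int], int]:
    """Unit-flow path encoding: one conceptual unit from s to t per index."""
    s, t = net.source, net.sink
    edges = net.edges
    x: dict[tuple[Edge, int], int] = {}
    for i in range(k):
        for e in edges:
            x[(e, i)] = lp.add_binary(f"x[{e[0]},{e[1]},{i}]")
    in_edges: dict[str, list[Edge]] = {}
    out_edges: dict[str, list[Edge]] = {}
    for e in edges:
        out_edges.setdefault(e[0], []).append(e)
        in_edges.setdefault(e[1], []).append(e)
    for i in range(k):
        lp.add_eq({x[(e, i)]: 1.0 for e in out_edges.get(s, [])}, 1.0)
        lp.add_eq({x[(e, i)]: 1.0 for e in in_edges.get(t, [])}, 1.0)
        for v in net.nodes:
            if v in (s, t):
                continue
            coeffs: dict[int, float] = {}
            for e in in_edges.get(v, []):
                coeffs[x[(e, i)]] = coeffs.get(x[(e, i)], 0) + 1.0
            for e in out_edges.get(v, []):
                coeffs[x[(e, i)]] = coeffs.get(x[(e, i)], 0) - 1.0
            if coeffs:
                lp.add_eq(coeffs, 0.0)
    return x


def _add_weights_and_products(model: KfdModel, config: SolverConfig) -> None:
    """Weight variables w_i plus the big-M product linearization pi = x * w."""
    lp, k, wbar = model.lp, model.k, model.wbar
    integer = model.weight_domain == "integer"
    w_lb = 1.0 if integer else 0.0
    for i in range(k):
        model.w[i] = lp.add_var(f"w[{i}]", w_lb, wbar, integer=integer)
    for (e, i), xj in model.x.items():
        pj = lp.add_var(f"pi[{e[0]},{e[1]},{i}]", 0.0, wbar, integer=integer)
        model.pi[(e, i)] = pj
        lp.add_row({pj: 1.0, xj: -wbar}, -math.inf, 0.0)           # pi <= wbar x
        lp.add_row({pj: 1.0, model.w[i]: -1.0}, -math.inf, 0.0)    # pi <= w
        # pi >= w - (1 - x) wbar  <=>  pi - w - wbar x >= -wbar
        lp.add_row({pj: 1.0, model.w[i]: -1.0, xj: -wbar}, -wbar, math.inf)
    if config.symmetry_breaking:
        for i in range(k - 1):
            lp.add_row({model.w[i]: 1.0, model.w[i + 1]: -1.0}, -math.inf, 0.0)


def _resolve_wbar(config: SolverConfig, default: int) -> int:
    if config.weight_upper_bound is not None:
        if config.weight_upper_bound < default:
            raise ValueError(
                f"weight_upper_bound {config.weight_upper_bound} is below the "
                f"required minimum {default}"
            )
        return config.weight_upper_bound
    return default


def build_kfd_model(net: FlowNetwork, k: int,
                    config: Optional[SolverConfig] = None) -> KfdModel:
    """Feasibility MILP for a k-path decomposition of a conserving network."""
    config = config or SolverConfig()
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if net.conserving is None:
        check_flow_conservation(net)
    if not net.conserving:
        raise ValueError(
            "network does not conserve flow; use the imperfect-flow variants"
        )
    lp = LinearProgram()
    wbar = _resolve_wbar(config, net.max_flow_value)
    model = KfdModel(net=net, k=k, lp=lp, wbar=wbar,
                     weight_domain=config.weight_domain)
    model._real_floor = config.real_weight_floor
    model.x = _add_path_encoding(lp, net, k)
    _add_weights_and_products(model, config)
    for e, f in net.flows.items():
        lp.add_eq({model.pi[(e, i)]: 1.0 for i in range(k)}, float(f))
    return model


def solve_model(model: KfdModel, config: Optional[SolverConfig] = None) -> SolveOutcome:
    config = config or SolverConfig()
    sol: LpSolution = model.lp.solve(time_limit=config.time_limit,
                                     mip_rel_gap=config.mip_rel_gap)
    status = sol.status
    if status == "time_limit" and sol.x is None:
        assignment = None
    elif sol.x is not None:
        assignment = {j: float(sol.x[j]) for j in range(model.lp.n_vars)}
    else:
        assignment = None
    if status == "optimal" and model.objective_kind == "feasibility":
        pass  # feasibility models report 'optimal' when a solution exists
    return SolveOutcome(status=status, assignment=assignment,
                        objective_value=sol.objective, wall_time=sol.wall_time)


def extract_decomposition(model: KfdModel, outcome: SolveOutcome,
                          net: Optional[FlowNetwork | IntervalFlowNetwork] = None
                          ) -> Decomposition:
    """Walk the x-assignment of each path index from source to sink.

    Binary values are thresholded at 0.5; integer-mode weights are rounded to
    the nearest integer (MILP backends return ~1e-6 noise).  Real-mode paths
    with (near-)zero weight are dropped.
    """
    if outcome.status not in ("optimal", "feasible"):
        raise ValueError(f"cannot extract from a {outcome.status} outcome")
    assert outcome.assignment is not None
    net = net if net is not None else model.net
    s, t = net.source, net.sink
    out_edges: dict[str, list[Edge]] = {}
    for e in net.edges:
        out_edges.setdefault(e[0], []).append(e)
    paths: list[Path] = []
    weights: list[float] = []
    for i in range(model.k):
        wv = outcome.assignment[model.w[i]]
        if model.weight_domain == "integer":
            weight: float = round(wv)
        else:
            weight = wv
            if weight <= 1e-6:
                continue
        nodes = [s]
        visited = {s}
        while nodes[-1] != t:
            used = [e for e in out_edges.get(nodes[-1], [])
                    if outcome.assignment[model.x[(e, i)]] >= 0.5]
            if len(used) != 1:
                raise ExtractionError(
                    f"path index {i}: node {nodes[-1]!r} has {len(used)} "
                    "selected out-edges"
                )
            nxt = used[0][1]
            if nxt in visited:
                raise ExtractionError(f"path index {i}: revisits node {nxt!r}")
            visited.add(nxt)
            nodes.append(nxt)
        paths.append(Path(tuple(nodes)))
        weights.append(weight)
    return Decomposition(paths, weights, model.weight_domain)
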