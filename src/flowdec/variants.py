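"""Practical variants layered on the k-FD model.

Four extensions of the basic decomposition MILP:

* **Subpath / generalized constraints** — edge sets (long reads, paired-end
  or multi-end fragments) that must be covered by a single decomposition
  path.  Per constraint R_j and path index i a binary r_ij with

      sum_{(u,v) in R_j} x_uvi >= |R_j| * r_ij       (coverage indicator)
      sum_i r_ij >= 1                                 (some path covers R_j)

  Because the formulation never uses contiguity of R_j's edges, legs need
  not be consecutive: any edge set that must co-occur in one path works.

* **Inexact (interval) flows** — the per-edge superposition equality is
  relaxed to  low_uv <= sum_i pi_uvi <= high_uv.

* **Imperfect flows, bounded error** — edge values need not conserve flow;
  a nonnegative slack e_uv >= |f_uv - sum_i pi_uvi| is introduced per edge
  and the total (or, optionally, per-edge) absolute error is capped at B.

* **Imperfect flows, minimum squared error** — minimize
  sum_uv (f_uv - sum_i pi_uvi)^2.  The objective is convex, and in integer
  mode every per-edge deviation is integral, so the square is encoded
  exactly as a piecewise-linear cost with unit steps of marginal cost
  1, 3, 5, ...  (d^2 = sum_{j=1..d} (2j-1)); increasing marginal costs make
  the LP fill cheap steps first, so no ordering constraints are needed.
  In real-weight mode the same encoding evaluates the convex piecewise
  interpolant of d^2 at integer breakpoints.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .ilp import (
    KfdModel,
    SolverConfig,
    _add_path_encoding,
    _add_weights_and_products,
    _resolve_wbar,
)
from .milp import LinearProgram
from .network import (
    Constraint,
    FlowNetwork,
    GraphStructureError,
    IntervalFlowNetwork,
)

__all__ = [
    "add_path_constraints",
    "build_inexact_model",
    "build_bounded_error_model",
    "build_min_error_model",
]


def add_path_constraints(model: KfdModel,
                         constraints: Sequence[Constraint]) -> KfdModel:
    """Install coverage constraints on an already-built model (in place)."""
    if not constraints:
        return model
    edges = set(model.net.edges)
    for c in constraints:
        for e in c.all_edges:
            if e not in edges:
                raise GraphStructureError(
                    f"constraint {c.constraint_id!r} references edge {e!r} "
                    "absent from the network"
                )
    lp = model.lp
    for c in constraints:
        size = c.size
        r_js = []
        for i in range(model.k):
            rj = lp.add_binary(f"r[{i},{c.constraint_id}]")
            model.r[(i, c.constraint_id)] = rj
            coeffs = {rj: -float(size)}
            for e in c.all_edges:
                xj = model.x[(e, i)]
                coeffs[xj] = coeffs.get(xj, 0.0) + 1.0
            lp.add_row(coeffs, 0.0, math.inf)  # sum x >= |R_j| r
            r_js.append(rj)
        lp.add_row({rj: 1.0 for rj in r_js}, 1.0, math.inf)
    if model.weight_domain == "real":
        # a 0-weight path could satisfy constraints for free; keep weights
        # meaningfully positive (floor configurable via SolverConfig)
        for i, wj in model.w.items():
            lp.lb[wj] = max(lp.lb[wj], model._real_floor)
    return model


def build_inexact_model(interval_net: IntervalFlowNetwork, k: int,
                        config: Optional[SolverConfig] = None) -> KfdModel:
    """k-path model whose superposition must lie within per-edge intervals."""
    config = config or SolverConfig()
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    lp = LinearProgram()
    wbar = _resolve_wbar(config, interval_net.max_high)
    model = KfdModel(net=interval_net, k=k, lp=lp, wbar=wbar,
                     weight_domain=config.weight_domain)
    model._real_floor = config.real_weight_floor
    model.x = _add_path_encoding(lp, interval_net, k)
    _add_weights_and_products(model, config)
    for e, (lo, hi) in interval_net.intervals.items():
        lp.add_row({model.pi[(e, i)]: 1.0 for i in range(k)}, float(lo), float(hi))
    return model


def _imperfect_base(net: FlowNetwork, k: int, config: SolverConfig,
                    wbar: int) -> KfdModel:
    lp = LinearProgram()
    model = KfdModel(net=net, k=k, lp=lp, wbar=wbar,
                     weight_domain=config.weight_domain)
    model._real_floor = config.real_weight_floor
    model.x = _add_path_encoding(lp, net, k)
    _add_weights_and_products(model, config)
    return model


def build_bounded_error_model(net: FlowNetwork, k: int, B: int,
                              config: Optional[SolverConfig] = None,
                              per_edge: bool = False) -> KfdModel:
    """k-path model tolerating total absolute error at most B.

    With ``per_edge=True`` the bound B applies to every edge individually
    instead of to the sum over edges.  B = 0 collapses to the exact model's
    feasibility on conserving inputs, and strictly generalizes it otherwise.
    """
    config = config or SolverConfig()
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if B < 0:
        raise ValueError(f"error bound B must be >= 0, got {B}")
    wbar = _resolve_wbar(config, net.max_flow_value + B)
    model = _imperfect_base(net, k, config, wbar)
    lp = model.lp
    err_vars = []
    for e, f in net.flows.items():
        ej = lp.add_var(f"e[{e[0]},{e[1]}]", 0.0, float(B))
        model.err[e] = ej
        pis = {model.pi[(e, i)]: 1.0 for i in range(k)}
        lp.add_row({ej: 1.0, **pis}, float(f), math.inf)          # e >= f - sum pi
        lp.add_row({ej: 1.0, **{j: -v for j, v in pis.items()}},
                   -float(f), math.inf)                            # e >= sum pi - f
        err_vars.append(ej)
    if not per_edge:
        lp.add_row({ej: 1.0 for ej in err_vars}, -math.inf, float(B))
    return model


def _min_error_upper_bound(net: FlowNetwork, k: int) -> int:
    """Error of a cheap feasible k-solution: all k paths along one route.

    Follows the widest out-edge from the source; the common route carries a
    total weight W >= k chosen to minimize the resulting squared error.  Any
    optimum therefore has total error <= this value, which bounds every
    per-edge deviation by its square root.
    """
    s, t = net.source, net.sink
    route = [s]
    while route[-1] != t:
        e = max(net.out_edges(route[-1]), key=lambda e: net.flows[e])
        route.append(e[1])
    on = [net.flows[e] for e in zip(route, route[1:])]
    off_sq = sum(f * f for e, f in net.flows.items()
                 if e not in set(zip(route, route[1:])))
    w_star = max(k, round(sum(on) / len(on)))
    best = min(
        sum((w - f) ** 2 for f in on) + off_sq
        for w in {max(k, w_star - 1), w_star, w_star + 1}
    )
    return int(best)


def build_min_error_model(net: FlowNetwork, k: int,
                          config: Optional[SolverConfig] = None) -> KfdModel:
    """k-path model minimizing the total squared per-edge deviation."""
    config = config or SolverConfig()
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    wbar = _resolve_wbar(config, net.max_flow_value)
    model = _imperfect_base(net, k, config, wbar)
    model.objective_kind = "quadratic_error"
    lp = model.lp
    objective: dict[int, float] = {}
    # per-edge deviations in an optimal solution cannot exceed the square
    # root of any feasible solution's total error
    dev_opt = math.isqrt(_min_error_upper_bound(net, k)) + 1
    for e, f in net.flows.items():
        # deviation sum_i pi - f = over - under, both >= 0
        dev_cap = min(max(float(f), k * wbar - float(f)), float(dev_opt))
        over = lp.add_var(f"dev+[{e[0]},{e[1]}]", 0.0, dev_cap)
        under = lp.add_var(f"dev-[{e[0]},{e[1]}]", 0.0, dev_cap)
        coeffs = {model.pi[(e, i)]: 1.0 for i in range(k)}
        coeffs[over] = -1.0
        coeffs[under] = 1.0
        lp.add_eq(coeffs, float(f))
        model.err[e] = over  # representative handle
        # unit steps of the squared cost: d^2 = sum_{j=1..d} (2j - 1)
        n_steps = int(math.ceil(dev_cap))
        step_coeffs = {over: -1.0, under: -1.0}
        for j in range(1, n_steps + 1):
            dj = lp.add_var(f"dsq[{e[0]},{e[1]},{j}]", 0.0, 1.0)
            objective[dj] = float(2 * j - 1)
            step_coeffs[dj] = 1.0
        lp.add_eq(step_coeffs, 0.0)  # sum_j delta_j = over + under
    lp.set_objective(objective)
    return model
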