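"""Synthetic splice-graph-like instances with planted ground-truth paths.

The generator emulates how perfect splice graphs are built from a known
transcriptome: sample k source-to-sink paths over a random topological order
(each path a candidate transcript), give each a positive integer abundance,
and superimpose them; the resulting network is conserving by construction and
its minimum decomposition size is at most k.  Weight schemes:

* ``uniform(lo, hi)`` — integers drawn uniformly;
* ``lognormal`` — exp(N(-4, 4)) scaled by 1000 and rounded to the nearest
  integer (clamped to >= 1), the standard simulated-expression model for
  transcript abundances.

Perturbation procedures supply inputs for the relaxed problems:

* interval flows — per edge, draw f' ~ N(f, (eps*f)^2) and form
  [round(0.9 f'), round(1.1 f')] (a 10% tolerance around the observed
  value); instances without a feasible integral flow are re-drawn;
* imperfect flows — add rounded Gaussian noise per edge, breaking
  conservation.

Everything is deterministic given the seed.  Trivial single-path graphs are
regenerated (they admit an immediate 1-path answer) unless k_planted = 1.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .network import (
    Constraint,
    Decomposition,
    FlowNetwork,
    IntervalFlowNetwork,
    Path,
)

__all__ = [
    "GeneratorConfig",
    "PlantedInstance",
    "GenerationError",
    "InstanceExcluded",
    "generate_planted_instance",
    "perturb_to_intervals",
    "sample_subpath_constraints",
    "perturb_to_imperfect",
    "interval_flow_feasible",
]

MAX_RETRIES = 200


def _rng(*parts) -> np.random.Generator:
    """Deterministic generator keyed by a mix of ints and string tags."""
    ints = [p if isinstance(p, int) else zlib.crc32(str(p).encode()) for p in parts]
    return np.random.default_rng(np.random.SeedSequence(ints))


class GenerationError(RuntimeError):
    """No valid instance could be generated within the retry cap."""


class InstanceExcluded(Exception):
    """Skip signal: the instance does not meet a procedure's precondition
    (e.g. fewer ground-truth paths than requested constraints)."""


@dataclass
class GeneratorConfig:
    n_nodes: int = 12
    k_planted: int = 4
    weight_scheme: str = "lognormal"   # or "uniform"
    weight_lo: int = 1                 # uniform scheme bounds (inclusive)
    weight_hi: int = 9
    lognormal_mean: float = -4.0
    lognormal_var: float = 4.0
    lognormal_scale: float = 1000.0
    epsilon: float = 0.05              # sd of the interval perturbation, as a fraction of f
    tolerance: float = 0.10            # half-width of the interval around f'
    n_constraints: int = 4
    junctions_per_constraint: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.k_planted < 1:
            raise ValueError("k_planted must be >= 1")
        if self.epsilon < 0 or self.tolerance < 0:
            raise ValueError("epsilon and tolerance must be >= 0")
        if self.n_constraints < 1 or self.junctions_per_constraint < 1:
            raise ValueError("constraint counts must be positive")
        if self.weight_scheme not in ("uniform", "lognormal"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")


@dataclass
class PlantedInstance:
    network: FlowNetwork
    truth_paths: list[Path]
    truth_weights: list[int]
    seed: int
    config: Optional[GeneratorConfig] = None

    @property
    def k_planted(self) -> int:
        return len(self.truth_paths)

    def truth_decomposition(self) -> Decomposition:
        # distinct planted paths may coincide as node sequences; merge them
        merged: dict[tuple, int] = {}
        for p, w in zip(self.truth_paths, self.truth_weights):
            merged[p.nodes] = merged.get(p.nodes, 0) + w
        return Decomposition([Path(n) for n in merged],
                             list(merged.values()), "integer")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _sample_weights(rng: np.random.Generator, cfg: GeneratorConfig, k: int) -> list[int]:
    if cfg.weight_scheme == "uniform":
        return [int(w) for w in rng.integers(cfg.weight_lo, cfg.weight_hi + 1, size=k)]
    sigma = math.sqrt(cfg.lognormal_var)
    vals = rng.lognormal(mean=cfg.lognormal_mean, sigma=sigma, size=k)
    return [max(1, _round_half_up(v * cfg.lognormal_scale)) for v in vals]


def _sample_path(rng: np.random.Generator, n: int) -> tuple[str, ...]:
    """Random s-t path along the topological order 0..n-1 (endpoints fixed)."""
    interior = [i for i in range(1, n - 1) if rng.random() < 0.5]
    return tuple(str(i) for i in [0, *interior, n - 1])


def generate_planted_instance(config: GeneratorConfig) -> PlantedInstance:
    """Superimpose k weighted random source-to-sink paths into a network."""
    for attempt in range(MAX_RETRIES):
        rng = _rng(config.seed, attempt)
        node_seqs = []
        tries = 0
        while len(node_seqs) < config.k_planted and tries < 50 * config.k_planted:
            cand = _sample_path(rng, config.n_nodes)
            if cand not in node_seqs:
                node_seqs.append(cand)
            tries += 1
        if len(node_seqs) < config.k_planted:
            continue
        weights = _sample_weights(rng, config, config.k_planted)
        paths = [Path(seq) for seq in node_seqs]
        flows: dict[tuple[str, str], int] = {}
        for p, w in zip(paths, weights):
            for e in p.edges:
                flows[e] = flows.get(e, 0) + w
        nodes = sorted({n for e in flows for n in e}, key=int)
        net = FlowNetwork(f"planted-{config.seed}", nodes, flows, conserving=True)
        if config.k_planted > 1 and _is_single_path(net):
            continue  # trivial graph: excluded, regenerate
        return PlantedInstance(net, paths, weights, config.seed, config)
    raise GenerationError(
        f"could not plant {config.k_planted} distinct paths on "
        f"{config.n_nodes} nodes within {MAX_RETRIES} attempts"
    )


def _is_single_path(net: FlowNetwork) -> bool:
    return all(
        len(net.out_edges(v)) <= 1 and len(net.in_edges(v)) <= 1
        for v in net.nodes
    )


def interval_flow_feasible(net: IntervalFlowNetwork) -> bool:
    """Does an integral s-t flow exist within every edge's [low, high]?

    Standard reduction of flow-with-lower-bounds to plain max-flow: route
    each edge's mandatory ``low`` units through auxiliary supply/demand
    nodes and check that all of them can be saturated.
    """
    g = nx.DiGraph()
    aux_s, aux_t = "__aux_s__", "__aux_t__"
    s, t = net.source, net.sink
    demand_total = 0
    excess: dict[str, int] = {}
    for (u, v), (lo, hi) in net.intervals.items():
        g.add_edge(u, v, capacity=hi - lo)
        excess[v] = excess.get(v, 0) + lo
        excess[u] = excess.get(u, 0) - lo
    g.add_edge(t, s, capacity=float("inf"))  # circulation closure
    for v, ex in excess.items():
        if ex > 0:
            g.add_edge(aux_s, v, capacity=ex)
            demand_total += ex
        elif ex < 0:
            g.add_edge(v, aux_t, capacity=-ex)
    if demand_total == 0:
        return True
    value, _ = nx.maximum_flow(g, aux_s, aux_t)
    return value == demand_total


def perturb_to_intervals(instance: PlantedInstance,
                         config: Optional[GeneratorConfig] = None
                         ) -> IntervalFlowNetwork:
    """Gaussian-perturb each flow and wrap it in a tolerance interval.

    Per edge, f' ~ N(f, (eps*f)^2) and the interval is
    [round((1-tol) f'), round((1+tol) f')], clamped at 0.  Draws yielding an
    infeasible interval network are re-drawn with an incremented sub-seed.
    """
    cfg = config or instance.config or GeneratorConfig(seed=instance.seed)
    net = instance.network
    for attempt in range(MAX_RETRIES):
        rng = _rng(cfg.seed, "intervals", attempt)
        intervals: dict[tuple[str, str], tuple[int, int]] = {}
        for e, f in net.flows.items():
            fp = rng.normal(loc=f, scale=cfg.epsilon * f) if cfg.epsilon > 0 else float(f)
            lo = max(0, _round_half_up((1.0 - cfg.tolerance) * fp))
            hi = max(lo, _round_half_up((1.0 + cfg.tolerance) * fp))
            intervals[e] = (lo, hi)
        inet = IntervalFlowNetwork(f"{net.graph_id}-intervals", list(net.nodes),
                                   intervals)
        if interval_flow_feasible(inet):
            return inet
    raise GenerationError(
        f"no feasible interval instance within {MAX_RETRIES} draws"
    )


def _nontrivial_junctions(net: FlowNetwork) -> set[str]:
    return {
        v for v in net.nodes
        if len(net.in_edges(v)) >= 2 or len(net.out_edges(v)) >= 2
    }


def sample_subpath_constraints(instance: PlantedInstance,
                               config: Optional[GeneratorConfig] = None
                               ) -> list[Constraint]:
    """Prefix constraints from ground-truth paths.

    For each of ``n_constraints`` distinct truth paths, the constraint is the
    shortest prefix whose interior contains ``junctions_per_constraint``
    nontrivial junctions (nodes with in- or out-degree >= 2); a path with
    fewer junctions contributes the whole path.  Raises
    :class:`InstanceExcluded` when the instance has fewer truth paths than
    constraints requested, mirroring the exclusion rule of the simulated
    benchmark construction.
    """
    cfg = config or instance.config or GeneratorConfig(seed=instance.seed)
    distinct = list(dict.fromkeys(p.nodes for p in instance.truth_paths))
    if len(distinct) < cfg.n_constraints:
        raise InstanceExcluded(
            f"instance has {len(distinct)} ground-truth paths, "
            f"fewer than the {cfg.n_constraints} constraints requested"
        )
    rng = _rng(cfg.seed, "constraints")
    chosen_idx = rng.choice(len(distinct), size=cfg.n_constraints, replace=False)
    junctions = _nontrivial_junctions(instance.network)
    out: list[Constraint] = []
    for ci, idx in enumerate(sorted(int(i) for i in chosen_idx)):
        nodes = distinct[idx]
        end = len(nodes)  # default: whole path
        count = 0
        for pos in range(1, len(nodes) - 1):
            if nodes[pos] in junctions:
                count += 1
                if count == cfg.junctions_per_constraint:
                    end = pos + 2  # shortest prefix with this interior junction
                    break
        prefix = nodes[:end]
        leg = list(zip(prefix, prefix[1:]))
        out.append(Constraint(f"{instance.network.graph_id}:c{ci}", [leg]))
    return out


def perturb_to_imperfect(instance: PlantedInstance, noise_sd_fraction: float,
                         seed: Optional[int] = None) -> FlowNetwork:
    """Add rounded Gaussian noise to each edge value (conservation breaks)."""
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    net = instance.network
    if noise_sd_fraction == 0:
        return FlowNetwork(f"{net.graph_id}-imperfect", list(net.nodes),
                           dict(net.flows))
    rng = _rng(seed if seed is not None else instance.seed, "imperfect")
    flows = {}
    for e, f in net.flows.items():
        noisy = f + _round_half_up(rng.normal(loc=0.0, scale=noise_sd_fraction * f))
        flows[e] = max(0, noisy)
    return FlowNetwork(f"{net.graph_id}-imperfect", list(net.nodes), flows)
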