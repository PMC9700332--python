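# Methods

## Problem and model

A *flow network* is a DAG `(V, E)` with unique source `s`, unique sink `t`
and a nonnegative integer value `f_uv` per edge satisfying conservation
(inflow = outflow) at every internal node. A *k-flow-decomposition* is a set
of k simple s–t paths with positive weights whose edge-wise weight sums
equal `f`. The package decides k-FD feasibility with a MILP and minimizes k
by scanning.

**Path encoding.** For each path index `i` and edge `(u,v)`, a binary
`x_uvi`. Constraints force, per index, one unit of conceptual flow from `s`
to `t`: unit out-flow at `s`, unit in-flow at `t`, and `x`-conservation at
internal nodes. On a DAG these unit flows are exactly the simple s–t paths,
so all exponentially many paths are represented with `k·|E|` binaries.

**Superposition and linearization.** Each index carries a weight `wᵢ`
(integer ≥ 1 by default; continuous ≥ 0 in real mode). The bilinear
requirement `Σᵢ x_uvi·wᵢ = f_uv` is linearized through `π_uvi` with the
standard big-M triple

```
π_uvi ≤ w̄·x_uvi,   π_uvi ≤ wᵢ,   π_uvi ≥ wᵢ − (1 − x_uvi)·w̄,
```

where `w̄` bounds any path weight. `w̄` defaults to the largest edge value
(no path weight can exceed the flow on its own first edge); the
bounded-error variant uses `max f + B`, intervals use `max high`. A tighter
`w̄` strengthens the relaxation, so `SolverConfig.weight_upper_bound` can
override it (values below the default are rejected as unsound).

**Minimal-k scan.** Feasibility is monotone in k (split any weight ≥ 2
across a duplicated path), so the driver scans k upward — by default from
the degree lower bound `max_v max(indeg⁺(v), outdeg⁺(v))` over
positive-flow edges, since a path uses at most one in- and one out-edge per
node — up to `min(|E|, |f|)` for exact MFD (`|f|` = flow out of `s`; a
unit-weight decomposition with `|f|` paths always exists), `|f|` with
subpath constraints, and `|E|` for interval/imperfect variants (any weighted
path set induces a flow, decomposable into ≤ |E| paths). Linear scan is the
default because minima are small in assembly graphs; binary search is
available for the plain problems. One wall-clock budget covers the whole
scan.

## Variants

**Coverage constraints.** A constraint is a set of edge-disjoint legs (edge
sequences) that must all occur in a single decomposition path — one leg for
a long read, two for a paired-end fragment, any set of edges for multi-end
protocols. Per constraint `R_j` and index `i`, a binary `r_ij` with
`Σ_{(u,v)∈R_j} x_uvi ≥ |R_j|·r_ij` and `Σᵢ r_ij ≥ 1`. Contiguity is never
used by the encoding; for single-leg constraints it is implied — a simple
path containing all edges of another path contains them consecutively, which
`validate_constraints` exploits. In real-weight mode constraints re-impose a
weight floor (default 1, `SolverConfig.real_weight_floor`), because a
0-weight path could otherwise "cover" a constraint without carrying flow.

**Interval flows.** The per-edge equality becomes
`low_uv ≤ Σᵢ π_uvi ≤ high_uv`. The degree lower bound then counts only
edges with `low > 0`.

**Bounded total error.** Conservation is not required of the input. A slack
`e_uv ≥ 0` with `e_uv ≥ f_uv − Σπ` and `e_uv ≥ Σπ − f_uv` linearizes the
absolute deviation; `Σ_uv e_uv ≤ B` caps the total. The problem statement
can also be read per-edge, so `per_edge=True` applies B to each edge
instead; the total-sum reading is the default. B = 0 on conserving input
coincides with exact k-FD.

**Minimum squared error.** Objective `Σ_uv (f_uv − Σᵢ π_uvi)²`. The
objective is convex, and with integer weights every per-edge deviation `d`
is integral, so `d²` is encoded exactly as a piecewise-linear cost:
deviation is split as `over − under` (both ≥ 0) and matched to unit steps
`δ_j ∈ [0,1]` with marginal costs 1, 3, 5, … (`d² = Σ_{j≤d} (2j−1)`);
increasing marginal costs make minimization fill cheap steps first, so no
ordering machinery is needed and any MILP backend solves the model exactly.
In real-weight mode the same encoding evaluates the convex piecewise
interpolant of `d²` at integer breakpoints (a slight underestimate between
integers). Step counts are kept small by an optimality cut: a cheap
feasible solution (all k paths along the widest route, best common weight)
gives an error upper bound `E_ub`, and no optimal deviation can exceed
`√E_ub`. Because error need not be monotone in k under integer weights
(each forced path carries ≥ 1), the driver evaluates every k up to `max_k`
(default `|E|`) unless the error hits 0, then reports the smallest k
attaining the minimum.

## Solver backend

Models are assembled in a small row-wise container and handed to
`scipy.optimize.milp` (HiGHS). Feasibility models use a zero objective;
HiGHS status codes map to `optimal / infeasible / time_limit / unbounded`.
No MIP gap is imposed beyond backend defaults; outcomes record the backend
status and wall time. Optional symmetry breaking (`w₁ ≤ … ≤ w_k`) removes
the path-index permutation symmetry; it never changes feasibility or
optimal objective values (verified by test) but speeds up infeasibility
proofs substantially, and the long driver scans in the test suite enable
it for that reason. Extraction thresholds binaries at 0.5, follows each
index's selected out-edges from `s` to `t`, rounds integer weights (backends
return ~1e-6 noise) and re-validates exactly; real-mode paths with weight
≤ 1e-6 are dropped. Enumeration of all optima re-solves with no-good cuts
over the full binary `x`-assignment and deduplicates solutions that are
equal as multisets of (path, weight) pairs.

## Brute-force oracle

Ground truth on tiny instances: enumerate all simple s–t paths
(lexicographic order), then search k-subsets and integer weight vectors
exhaustively. Weight spaces are complete by construction — exact mode uses
compositions of `|f|` into k positive parts (weights out of `s` must sum to
`|f|`); interval mode bounds weights by `max high`; bounded mode by
`max f + B` (anything larger forces error > B); min-error mode by `max f`
(reducing a larger weight strictly reduces every deviation it causes).
Edge-wise pruning (partial sums checked the moment an edge's last using
path is weighted) keeps tiny instances fast. Hard caps (10 000 paths, total
flow 2 000) raise errors rather than truncate, so the oracle is never
approximate. For per-k squared-error comparisons the oracle can search path
multisets (`distinct=False`), matching a MILP that may duplicate a path
across indices.

## Synthetic instances

The generator emulates perfect splice graphs built by superimposing known
transcripts: k random s–t paths along a fixed topological order (each
interior node kept with probability ½), integer abundances, edge flows =
weighted superposition — hence conserving by construction and `min_k ≤ k`
always. Weight schemes: `uniform(lo, hi)`; or `lognormal` with mean −4 and
variance 4 scaled by 1000 and rounded (clamped ≥ 1 — a zero-abundance
transcript is no path), the usual simulated-expression model for transcript
abundances. Single-path graphs are regenerated when `k_planted > 1`
(they are trivially solvable and excluded from benchmark constructions).
Defaults `n_nodes = 12`, `k_planted = 4` are typical of moderately complex
gene loci; the test and acceptance sweeps use smaller sizes (6–8 nodes,
k ≤ 4, uniform weights ≤ 9) so the exhaustive oracle remains exact ground
truth on every instance while the full suite stays fast.

Perturbations: *intervals* — per edge draw `f' ~ N(f, (ε·f)²)` (ε = 0.05 by
default) and take `[round(0.9·f'), round(1.1·f')]`, clamped at 0, rounding
half-up; instances without an integral flow inside the bounds (checked by a
lower/upper-bounded flow feasibility reduction to max-flow, independent of
any MILP) are re-drawn deterministically. *Subpath constraints* — for four
ground-truth paths, the shortest prefix whose interior crosses three
nontrivial junctions (in- or out-degree ≥ 2), the whole path if it has
fewer; instances with fewer truth paths than requested constraints raise a
skip signal. *Imperfect flows* — rounded Gaussian noise per edge, clamped
at 0 (the natural choice for count data), breaking conservation.

What the generator does *not* emulate: read sampling, coverage dips,
mapping ambiguity, genome coordinates, or cyclic (de novo) graphs. Passing
tests therefore certify the solvers' correctness on conserving /
perturbed DAG flows, not robustness to real sequencing artefacts.

## Numerical and degenerate-input choices

- Zero-flow edges are dropped at parse time by default (a positive-weight
  decomposition cannot use them; superposition would force 0 anyway);
  `keep_zero_edges` retains them.
- Parallel edges are rejected: all variables are indexed by `(u, v)`.
- Multiple sources/sinks are normalized with a super-source/sink whose edges
  carry the adjacent node's total out-/in-flow; reported paths have the
  auxiliary nodes stripped.
- Node ids are opaque strings; the vertex-count line of instance files is
  validated loosely (ids need not be `0..n−1`).
- Ties among equally small decompositions are broken by the backend; with a
  fixed solver seed results are stable up to path-index permutation.
- The "round to nearest" in interval construction is half-up, applied
  consistently by the generator and its tests.

## Known limitations

- Cyclic graphs are out of scope (the path encoding characterizes s–t paths
  only in DAGs).
- The min-error MILP grows with `√E_ub` unit-step variables per edge; on
  badly non-conserving large instances this is the slowest variant.
- Real-weight mode's squared-error objective is exact only at integer
  deviations.
- The oracle is exponential by design and guarded by hard caps; it is a
  verification tool, not a solver.
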