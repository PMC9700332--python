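"""Force a long read (and a paired-end read) to be covered by one path.

A subpath constraint models a read spanning several junctions: some
decomposition path must contain all of its edges.  A two-leg constraint
models a paired-end read — both fragments must come from the same path,
which here is impossible and makes the instance infeasible.
"""

from flowdec import Constraint, FlowNetwork, solve_mfd_subpath, validate_constraints

net = FlowNetwork(
    "example", ["s", "a", "b", "t"],
    {("s", "a"): 6, ("s", "b"): 7, ("a", "b"): 2, ("a", "t"): 4, ("b", "t"): 9},
)

long_read = Constraint("long-read", [[("a", "b"), ("b", "t")]])
result = solve_mfd_subpath(net, [long_read])
print(f"min paths with the a-b-t read covered: {result.min_k}")
print("constraint satisfied:",
      validate_constraints(result.decomposition, [long_read]).ok)

diamond = FlowNetwork(
    "diamond", ["s", "a", "b", "t"],
    {("s", "a"): 3, ("a", "t"): 3, ("s", "b"): 2, ("b", "t"): 2},
)
paired = Constraint("paired-end", [[("s", "a")], [("b", "t")]])
print("paired-end read crossing both branches:",
      solve_mfd_subpath(diamond, [paired]).status)
# No single s-t path can use both branches of the diamond, so the
# constrained problem is correctly reported infeasible.
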