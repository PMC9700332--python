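"""Imperfect flows: edge values that do not conserve flow.

Sequencing and mapping noise can break Kirchhoff balance.  Two remedies:
cap the total absolute error at a budget B, or find the smallest k among
the path sets minimizing the total squared error.
"""

from flowdec import FlowNetwork, solve_imperfect_bounded, solve_imperfect_minerr

net = FlowNetwork(
    "imperfect", ["s", "a", "b", "t"],
    {("s", "a"): 3, ("a", "t"): 3, ("s", "b"): 1, ("b", "t"): 1},
)

for B in (2, 1, 0):
    res = solve_imperfect_bounded(net, B)
    print(f"error budget B={B}: min paths = {res.min_k} ({res.status})")
# B=2 lets a single path of weight 3 absorb the weak (s,b,t) branch;
# B<=1 forces both branches to be represented.

res = solve_imperfect_minerr(net)
print(f"minimum squared error: {res.objective:g} at k = {res.min_k}")

chain = FlowNetwork("chain", ["s", "a", "t"], {("s", "a"): 5, ("a", "t"): 6})
res = solve_imperfect_minerr(chain)
print(f"unbalanced chain: squared error {res.objective:g} with "
      f"weight {res.decomposition.weights[0]}")
# A single path cannot match both 5 and 6; the best integer weight leaves
# a squared error of exactly 1.
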