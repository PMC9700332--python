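"""Generate a planted instance and verify the solver against the oracle.

The generator superimposes k random weighted transcripts into a conserving
network, so k upper-bounds the true minimum.  On tiny instances the
brute-force oracle enumerates every path subset and weight assignment,
giving exact ground truth.
"""

from flowdec import (
    GeneratorConfig,
    generate_planted_instance,
    perturb_to_intervals,
    solve_mfd,
    solve_mifd,
)
from flowdec.oracle import oracle_min_k

cfg = GeneratorConfig(n_nodes=8, k_planted=3, weight_scheme="uniform",
                      weight_lo=1, weight_hi=9, seed=11)
inst = generate_planted_instance(cfg)
net = inst.network
print(f"planted {inst.k_planted} paths on {len(net.nodes)} nodes, "
      f"{len(net.edges)} edges; weights {inst.truth_weights}")

res = solve_mfd(net)
orc = oracle_min_k(net)
print(f"solver min k = {res.min_k}, oracle min k = {orc.min_k}")
# The MILP and the exhaustive search must agree exactly; the planted k is
# only an upper bound (superimposed paths can merge into fewer).

ivals = perturb_to_intervals(inst)
print(f"after 5% Gaussian perturbation + 10% tolerance intervals: "
      f"min k = {solve_mifd(ivals).min_k}")
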