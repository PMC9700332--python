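"""Interval (inexact) flows: coverage is only trusted up to a tolerance.

Replacing each edge value with an interval can shrink the decomposition:
the exact version of this network needs 3 paths, the relaxed one only 2.
"""

from flowdec import IntervalFlowNetwork, solve_mifd, validate_decomposition

inet = IntervalFlowNetwork(
    "example-intervals", ["s", "a", "b", "t"],
    {("s", "a"): (4, 6), ("s", "b"): (5, 7), ("a", "b"): (0, 2),
     ("a", "t"): (4, 4), ("b", "t"): (7, 9)},
)

result = solve_mifd(inet)
print(f"minimum number of paths within intervals: {result.min_k}")
for path, w in zip(result.decomposition.paths, result.decomposition.weights):
    print(f"  weight {w}: {' -> '.join(path.nodes)}")
print("superposition within every interval:",
      validate_decomposition(None, result.decomposition, "interval", inet).ok)
# The 2-path answer puts each edge's weighted coverage inside its
# [low, high] band — fewer transcripts than the exact flow would force.
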