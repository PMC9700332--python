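import pytest

from flowdec import FlowNetwork, GeneratorConfig, IntervalFlowNetwork, generate_planted_instance


@pytest.fixture
def g5():
    """Worked 4-node example: unique 3-path decomposition (weights 2, 4, 7)."""
    return FlowNetwork(
        "G5", ["s", "a", "b", "t"],
        {("s", "a"): 6, ("s", "b"): 7, ("a", "b"): 2, ("a", "t"): 4, ("b", "t"): 9},
    )


@pytest.fixture
def g5_intervals():
    """Interval relaxation of G5 that admits a 2-path answer."""
    return IntervalFlowNetwork(
        "G5i", ["s", "a", "b", "t"],
        {("s", "a"): (4, 6), ("s", "b"): (5, 7), ("a", "b"): (0, 2),
         ("a", "t"): (4, 4), ("b", "t"): (7, 9)},
    )


@pytest.fixture
def diamond():
    return FlowNetwork(
        "diamond", ["s", "a", "b", "t"],
        {("s", "a"): 3, ("a", "t"): 3, ("s", "b"): 2, ("b", "t"): 2},
    )


@pytest.fixture
def fan():
    return FlowNetwork(
        "fan", ["s", "a", "b", "c", "t"],
        {("s", "a"): 1, ("s", "b"): 2, ("s", "c"): 4,
         ("a", "t"): 1, ("b", "t"): 2, ("c", "t"): 4},
    )


@pytest.fixture
def chain():
    """Non-conserving 2-edge chain (imbalance -1 at the middle node)."""
    return FlowNetwork("chain", ["s", "a", "t"], {("s", "a"): 5, ("a", "t"): 6})


@pytest.fixture
def two_lane():
    """Non-conserving pair of parallel lanes (3,3) and (1,1)."""
    return FlowNetwork(
        "two-lane", ["s", "a", "b", "t"],
        {("s", "a"): 3, ("a", "t"): 3, ("s", "b"): 1, ("b", "t"): 1},
    )


def planted(seed, **kw):
    defaults = dict(n_nodes=7, k_planted=1 + seed % 3, weight_scheme="uniform",
                    weight_lo=1, weight_hi=5, seed=seed)
    defaults.update(kw)
    return generate_planted_instance(GeneratorConfig(**defaults))
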