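import pytest

from hypernull import (
    Hypergraph,
    SyntheticSpec,
    build_hypergraph,
    generate_synthetic_hypergraph,
    toy_figure1_hypergraph,
)


def random_hypergraph(seed, n=30, m=40, sizes=None, hetero=0.0) -> Hypergraph:
    """Seeded random hypergraph used throughout the suite."""
    if sizes is None:
        sizes = {2: 0.3, 3: 0.4, 4: 0.2, 6: 0.1}
    spec = SyntheticSpec(
        n=n, m=m, sizes=sizes, rng_seed=seed, node_weight_exponent=hetero
    )
    return generate_synthetic_hypergraph(spec)


@pytest.fixture
def t1() -> Hypergraph:
    """4 nodes, 3 hyperedges: {1,2,3}, {3,4}, {1,4} (labels 1..4 -> indices 0..3)."""
    return build_hypergraph([{1, 2, 3}, {3, 4}, {1, 4}])


@pytest.fixture
def toy() -> Hypergraph:
    return toy_figure1_hypergraph()


@pytest.fixture
def star_of_dyads() -> Hypergraph:
    """Hub node 0 paired with each of 9 leaves through dyadic hyperedges."""
    return Hypergraph(list(range(10)), [{0, i} for i in range(1, 10)])
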