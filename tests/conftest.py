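import random

import networkx as nx
import pytest

from pilesort.sortdata import SortingStudy, make_study


@pytest.fixture
def tiny_study() -> SortingStudy:
    """Two researchers, three quotes: both pair quotes 1 and 2 together."""
    return make_study(
        [
            ("r1", 1, "A"),
            ("r1", 2, "A"),
            ("r1", 3, "B"),
            ("r2", 1, "X"),
            ("r2", 2, "X"),
            ("r2", 3, "Y"),
        ]
    )


def random_study(n_quotes: int, n_researchers: int, n_piles: int, seed: int):
    """Uniform random sorting study satisfying the open-sorting protocol."""
    rng = random.Random(seed)
    rows = []
    for r in range(n_researchers):
        while True:  # resample until every researcher uses >= 2 piles
            piles = [rng.randrange(n_piles) for _ in range(n_quotes)]
            if len(set(piles)) >= 2:
                break
        rows.extend(
            (f"r{r}", q + 1, str(piles[q])) for q in range(n_quotes)
        )
    return make_study(rows)


def random_weighted_graph(n: int, p: float, seed: int, max_w: int = 4) -> nx.Graph:
    """Random graph with integer weights; guaranteed at least one edge."""
    rng = random.Random(seed)
    g = nx.gnp_random_graph(n, p, seed=rng.randrange(10**6))
    for u, v in g.edges:
        g[u][v]["weight"] = rng.randint(1, max_w)
    if g.number_of_edges() == 0:
        g.add_edge(0, 1 % n if n > 1 else 0, weight=1)
    return g
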