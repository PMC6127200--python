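import numpy as np
import pytest

from qacolink import Graph


def build_graph(edges, extra_nodes=()):
    return Graph.from_edges(edges, extra_nodes=extra_nodes)


@pytest.fixture
def path3():
    """a – b – c"""
    return build_graph([("a", "b"), ("b", "c")])


@pytest.fixture
def path4():
    """a – b – c – d"""
    return build_graph([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def cycle4():
    """4-cycle a – b – c – d – a"""
    return build_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def triangle():
    return build_graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def ch_gadget():
    """x and y share neighbours z1, z2 which are themselves connected."""
    return build_graph(
        [("x", "z1"), ("x", "z2"), ("y", "z1"), ("y", "z2"), ("z1", "z2")]
    )


def visibility_oracle(g, iota, omega):
    """Exhaustive common-neighbour + simple-length-3-path enumeration.

    Independent of the matrix-algebra implementation: nested loops over
    explicit neighbour sets.
    """
    n = g.n_nodes
    deg = g.degrees()
    nbrs = [g.neighbors(i) for i in range(n)]

    def wt(z):
        return 1.0 if iota == 0 else 1.0 / deg[z]

    eta = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s = sum(wt(z) for z in nbrs[i] & nbrs[j])
            t = 0.0
            for x in nbrs[i]:
                if x == j:
                    continue
                for y in nbrs[j]:
                    if y == i or y == x:
                        continue
                    if y in nbrs[x]:
                        t += 1.0 / ((deg[x] * deg[y]) ** iota)
            eta[i, j] = s + omega * t
    return eta


def random_connected_graph(n, rng):
    """A connected simple graph on n labelled nodes (rejection sampling)."""
    import networkx as nx

    while True:
        p = rng.uniform(0.25, 0.9)
        seed = int(rng.integers(0, 2 ** 31))
        nxg = nx.gnp_random_graph(n, p, seed=seed)
        if nx.is_connected(nxg):
            return build_graph(
                [(str(u), str(v)) for u, v in nxg.edges()],
                extra_nodes=[str(i) for i in range(n)],
            )
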