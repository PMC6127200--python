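"""Network data model, edge-list I/O, and train/probe splitting.

Networks are undirected, simple and unweighted: no self-loops, no parallel
edges.  Node labels are arbitrary strings; internally every node carries a
0-based integer index fixed by order of first appearance, and all matrix-valued
quantities (pheromone, visibility, scores) are indexed that way.  Outputs map
back to labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: comment prefixes skipped by the edge-list reader (common dialects)
COMMENT_PREFIXES = ("#", "%")


class GraphError(ValueError):
    """Domain error on graph construction or manipulation."""


class EdgeListParseError(GraphError):
    """Malformed edge-list line; the message names the line number."""


class Graph:
    """An undirected simple graph with string labels and a stable index.

    Parameters
    ----------
    labels:
        Node labels in index order.  Duplicates are rejected.
    edges:
        Iterable of (u, v) label pairs.  Self-loops are rejected; duplicate
        and reversed-duplicate pairs collapse to a single stored edge.
    """

    __slots__ = ("_labels", "_index", "_adj")

    def __init__(self, labels, edges=()):
        self._labels: tuple[str, ...] = tuple(str(x) for x in labels)
        self._index: dict[str, int] = {lab: i for i, lab in enumerate(self._labels)}
        if len(self._index) != len(self._labels):
            raise GraphError("duplicate node labels")
        self._adj: list[set[int]] = [set() for _ in self._labels]
        for u, v in edges:
            self.__add_edge(str(u), str(v))

    def __add_edge(self, u: str, v: str) -> None:
        try:
            i, j = self._index[u], self._index[v]
        except KeyError as exc:
            raise GraphError(f"edge endpoint {exc} is not a declared node") from None
        if i == j:
            raise GraphError(f"self-loop on node {u!r}")
        self._adj[i].add(j)
        self._adj[j].add(i)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_edges(cls, edges, extra_nodes=()) -> "Graph":
        """Build a graph from label pairs; node order = first appearance."""
        labels: list[str] = []
        seen: set[str] = set()

        def note(x: str) -> None:
            if x not in seen:
                seen.add(x)
                labels.append(x)

        pairs = [(str(u), str(v)) for u, v in edges]
        for u, v in pairs:
            note(u)
            note(v)
        for x in extra_nodes:
            note(str(x))
        return cls(labels, pairs)

    # -- basic queries -------------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def n_nodes(self) -> int:
        return len(self._labels)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._adj) // 2

    def index_of(self, label: str) -> int:
        return self._index[str(label)]

    def has_edge(self, i: int, j: int) -> bool:
        return j in self._adj[i]

    def neighbors(self, i: int) -> frozenset[int]:
        return frozenset(self._adj[i])

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self._adj], dtype=float)

    def edges_idx(self) -> list[tuple[int, int]]:
        """All edges as (i, j) index pairs with i < j, sorted."""
        return sorted((i, j) for i, s in enumerate(self._adj) for j in s if i < j)

    def edge_labels(self) -> set[tuple[str, str]]:
        """Edges as label pairs, each pair in label-sorted order."""
        out = set()
        for i, j in self.edges_idx():
            u, v = self._labels[i], self._labels[j]
            out.add((u, v) if u <= v else (v, u))
        return out

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, s in enumerate(self._adj):
            for j in s:
                a[i, j] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._labels)
        g.add_edges_from((self._labels[i], self._labels[j]) for i, j in self.edges_idx())
        return g

    def subgraph(self, keep_labels) -> "Graph":
        """Induced subgraph; node order inherited from this graph."""
        keep = set(str(x) for x in keep_labels)
        labels = [lab for lab in self._labels if lab in keep]
        edges = [
            (self._labels[i], self._labels[j])
            for i, j in self.edges_idx()
            if self._labels[i] in keep and self._labels[j] in keep
        ]
        return Graph(labels, edges)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n={self.n_nodes}, m={self.n_edges})"


# ---------------------------------------------------------------------------
# edge-list I/O


def read_edge_list(path) -> Graph:
    """Read a whitespace-separated two-column edge list into a :class:`Graph`.

    Lines starting with ``#`` or ``%`` and blank lines are skipped.  Tokens
    beyond the first two (e.g. weights) are ignored.  Self-loop lines are
    dropped with a warning; duplicate and reversed-duplicate lines collapse.

    Raises
    ------
    OSError
        If the file cannot be read.
    EdgeListParseError
        If a non-comment line has fewer than two tokens (names the line).
    """
    labels: list[str] = []
    seen: set[str] = set()
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(COMMENT_PREFIXES):
                continue
            toks = line.split()
            if len(toks) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected at least 2 tokens, got {len(toks)}"
                )
            u, v = toks[0], toks[1]
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    labels.append(x)
            if u == v:
                logger.warning("%s: line %d: dropping self-loop on %r", path, lineno, u)
                continue
            pairs.append((u, v))
    return Graph(labels, pairs)


def write_edge_list(g: Graph, path) -> None:
    """Write one edge per line, endpoints label-sorted, lines sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(g.edge_labels()):
            fh.write(f"{u} {v}\n")


# ---------------------------------------------------------------------------
# components


def largest_component(g: Graph) -> Graph:
    """Induced subgraph on the largest connected component.

    Ties on component size are broken deterministically in favour of the
    component containing the lexicographically smallest node label.
    """
    if g.n_nodes == 0:
        raise GraphError("empty graph has no components")
    comps = [sorted(c) for c in nx.connected_components(g.to_networkx())]
    best = min(comps, key=lambda c: (-len(c), min(c)))
    return g.subgraph(best)


# ---------------------------------------------------------------------------
# train/probe splitting


@dataclass(frozen=True)
class EdgeSplit:
    """Random partition of observed edges into a training and a probe set.

    ``train`` and ``probe`` hold label pairs (each label-sorted); together
    they exactly cover the edge set of the graph that was split.
    """

    train: frozenset[tuple[str, str]]
    probe: frozenset[tuple[str, str]]
    fraction: float
    seed: int

    def __post_init__(self):
        if self.train & self.probe:
            raise GraphError("train and probe sets overlap")


def split_edges(g: Graph, fraction: float, seed: int) -> EdgeSplit:
    """Uniformly split edges into training (|E^T| = round(fraction·|E|)) and probe.

    The same (graph, fraction, seed) always yields the identical split.  No
    connectivity of the training graph is enforced.
    """
    if not 0.0 < fraction < 1.0:
        raise GraphError(f"fraction must be in (0,1), got {fraction}")
    m = g.n_edges
    if m < 2:
        raise GraphError("need at least 2 edges to split")
    n_train = int(math.floor(fraction * m + 0.5))
    if n_train in (0, m):
        raise GraphError(
            f"fraction {fraction} leaves an empty side for |E|={m}"
        )
    edges = sorted(g.edge_labels())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    train = frozenset(edges[i] for i in perm[:n_train])
    probe = frozenset(edges[i] for i in perm[n_train:])
    return EdgeSplit(train=train, probe=probe, fraction=fraction, seed=seed)


def training_graph(g: Graph, split: EdgeSplit) -> Graph:
    """Graph on all of g's nodes containing only the training edges.

    Probe endpoints that become isolated are kept: they remain scoreable
    candidates.
    """
    return Graph(g.labels, split.train)
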