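"""Synthetic testbeds: Watts–Strogatz small worlds and nPSO-style hyperbolic
community networks.

The WS generator rewires a ring lattice and is delegated to networkx (the
construction is the textbook one).  The nPSO-style generator grows a network
in the hyperbolic disk: node t appears at radius r_t = 2·ln t, earlier nodes
drift inward under popularity fading with exponent 1/(γ−1) (yielding a
degree-distribution power law with exponent γ), and angular coordinates are
drawn from a mixture of von Mises components with equally spaced means — the
components are the planted communities.  Each new node links to exactly
m_half existing nodes sampled with Fermi-like weights exp(−(d−d_min)/(2T)) in
hyperbolic distance d; the temperature T flattens the weights, so low T means
tightly local attachment and high clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import Graph, GraphError

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class WSParams:
    """Watts–Strogatz settings: each node is wired to its m_half nearest ring
    neighbours on each side (average degree 2·m_half); each edge is rewired
    independently with probability beta."""

    N: int
    m_half: int
    beta: float
    seed: int = 0

    def validate(self) -> None:
        if 2 * self.m_half >= self.N:
            raise GraphError(
                f"need 2*m_half < N, got m_half={self.m_half}, N={self.N}"
            )
        if self.m_half < 1:
            raise GraphError("m_half must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise GraphError(f"beta must be in [0,1], got {self.beta}")


def generate_ws(p: WSParams) -> Graph:
    """Rewired ring lattice with |E| = N·m_half, simple and undirected."""
    p.validate()
    nxg = nx.watts_strogatz_graph(p.N, 2 * p.m_half, p.beta, seed=p.seed)
    labels = [str(i) for i in range(p.N)]
    return Graph(labels, ((str(u), str(v)) for u, v in nxg.edges()))


@dataclass(frozen=True)
class NPSOParams:
    """nPSO-style settings.

    gamma is the target degree-distribution exponent (> 2), T the attachment
    temperature (> 0, inversely related to clustering), n_comm the number of
    planted angular communities.  angular_spread is the standard deviation of
    each mixture component; the default (2π/n_comm)/6 keeps neighbouring
    communities well separated.
    """

    N: int
    m_half: int
    T: float
    gamma: float = 3.0
    n_comm: int = 8
    seed: int = 0
    angular_spread: float | None = None

    def validate(self) -> None:
        if self.T <= 0:
            raise GraphError(f"T must be positive, got {self.T}")
        if self.gamma <= 2:
            raise GraphError(f"gamma must be > 2, got {self.gamma}")
        if self.n_comm < 1:
            raise GraphError("n_comm must be >= 1")
        if self.N < self.m_half + 1:
            raise GraphError(
                f"need N >= m_half+1, got N={self.N}, m_half={self.m_half}"
            )
        if self.m_half < 1:
            raise GraphError("m_half must be >= 1")

    @property
    def spread(self) -> float:
        return (
            self.angular_spread
            if self.angular_spread is not None
            else (TWO_PI / self.n_comm) / 6.0
        )


def _hyperbolic_distance(r1, theta1, r2, theta2):
    """Distance in the native hyperbolic disk; vectorised, clipped at 0."""
    dtheta = np.pi - np.abs(np.pi - np.abs(theta1 - theta2))
    cosh_d = np.cosh(r1) * np.cosh(r2) - np.sinh(r1) * np.sinh(r2) * np.cos(dtheta)
    return np.arccosh(np.clip(cosh_d, 1.0, None))


def generate_npso(p: NPSOParams):
    """Grow an nPSO-style network.

    Returns ``(graph, coords, communities)``: the graph (labels "0"… in birth
    order), an (N, 2) array of final (radius, angle) coordinates, and the
    ground-truth community label of each node (the mixture component of its
    angular draw).
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    n = p.N
    fade = 1.0 / (p.gamma - 1.0)
    kappa_vm = 1.0 / p.spread ** 2
    means = TWO_PI * np.arange(p.n_comm) / p.n_comm
    comm = rng.integers(0, p.n_comm, size=n)
    theta = np.mod(rng.vonmises(means[comm], kappa_vm), TWO_PI)
    birth_r = 2.0 * np.log(np.arange(1, n + 1))

    edges: list[tuple[str, str]] = []
    for t in range(1, n):
        r_new = birth_r[t]
        # popularity fading: existing node s sits at β·r_s + (1−β)·r_t
        r_exist = fade * birth_r[:t] + (1.0 - fade) * r_new
        if t <= p.m_half:
            targets = np.arange(t)
        else:
            d = _hyperbolic_distance(r_exist, theta[:t], r_new, theta[t])
            log_w = -(d - d.min()) / (2.0 * p.T)
            # Gumbel-top-k = successive weighted sampling without replacement
            gumbel = -np.log(-np.log(rng.random(t)))
            targets = np.argpartition(log_w + gumbel, t - p.m_half)[-p.m_half:]
        edges.extend((str(s), str(t)) for s in targets)

    labels = [str(i) for i in range(n)]
    graph = Graph(labels, edges)
    final_r = fade * birth_r + (1.0 - fade) * birth_r[-1]
    coords = np.column_stack([final_r, theta])
    return graph, coords, comm


def write_coordinate_sidecar(path, graph: Graph, coords: np.ndarray, comm: np.ndarray) -> None:
    """Tab-separated diagnostics: node, radius, angle, community."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node\tradius\tangle\tcommunity\n")
        for i, lab in enumerate(graph.labels):
            fh.write(f"{lab}\t{coords[i, 0]:.10g}\t{coords[i, 1]:.10g}\t{int(comm[i])}\n")
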