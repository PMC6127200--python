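"""Quantum-inspired ant colony optimization (QACO) for link prediction.

The predictor lets a colony of m ants perform tabu random walks on the
*completion* of the training network (every node pair is walkable).  Three
quantities bias each step from node i to node j:

* link pheromone ``τ_ij`` — initialised uniformly to δ on every pair, decayed
  by the trajectory persistence ρ each iteration and reinforced along realised
  ant paths in proportion to the path fitness;
* visibility ``η_ij`` — a static quasi-local similarity mixing degree-weighted
  common neighbours with degree-weighted simple paths of length 3;
* quantum node pheromone ``μ_j = 1/|α_j|²`` — each node holds one qubit
  (α, β) per ant, initialised to the balanced state (1/√2, 1/√2) and rotated
  by a quantum rotation gate whenever that ant visits the node.  Rotation
  drives amplitude from |0⟩ toward |1⟩, so visited nodes become more
  attractive without the runaway feedback of classical pheromone alone.

The transition weight is ``τ_ij^λ · η_ij^κ · μ_j^ν`` normalised over the
unvisited nodes.  After N_c iterations the score of a disconnected pair is
``τ_ij + ε·η_ij``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .graph import Graph, GraphError
from .scores import ScoreMatrix, candidate_mask_from_adjacency

logger = logging.getLogger(__name__)

#: lower bound on |α|² in the node-intensity formula μ = 1/|α|²; prevents
#: blow-up as a qubit approaches |1⟩
ALPHA_SQ_FLOOR = 1e-6

INV_SQRT2 = 1.0 / math.sqrt(2.0)


class QACOError(ValueError):
    """Domain error in QACO parameters or state."""


@dataclass(frozen=True)
class QACOParams:
    """Tunable parameters of the QACO predictor.

    Defaults follow the published experimental setting:
    (δ, λ, κ, ν, ρ, ε) = (1, 1, 2, 1, 0.9, 0.2), ω = 0.01, and a rotation
    magnitude Δθ fixed at the midpoint of the recommended [0.01π, 0.08π]
    range.  ι switches the degree weighting of the visibility between raw
    counts (0) and resource-allocation-like weighting (1).
    """

    delta: float = 1.0        # initial link pheromone δ
    lam: float = 1.0          # pheromone exponent λ
    kappa: float = 2.0        # visibility exponent κ
    nu: float = 1.0           # node-intensity exponent ν
    rho: float = 0.9          # trajectory persistence ρ ∈ [0, 1)
    eps: float = 0.2          # score mixing weight ε
    omega: float = 0.01       # weight ω of the length-3-path visibility term
    iota: int = 1             # degree exponent ι ∈ {0, 1}
    dtheta: float = 0.05 * math.pi   # rotation magnitude Δθ
    C: float = 1.0            # fitness gain constant
    n_ants: int = 50          # colony size m
    n_iter: int = 20          # iteration budget N_c
    path_len: int | None = None   # steps per ant per iteration (None → n)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise QACOError(f"rho must be in [0,1), got {self.rho}")
        if not 0.01 * math.pi <= self.dtheta <= 0.08 * math.pi:
            raise QACOError(
                f"dtheta must be in [0.01*pi, 0.08*pi], got {self.dtheta}"
            )
        if self.iota not in (0, 1):
            raise QACOError(f"iota must be 0 or 1, got {self.iota}")
        if self.delta <= 0:
            raise QACOError(f"delta must be positive, got {self.delta}")
        if self.n_ants < 1:
            raise QACOError("n_ants must be >= 1")
        if self.n_iter < 0:
            raise QACOError("n_iter must be >= 0")
        if self.path_len is not None and self.path_len < 1:
            raise QACOError("path_len must be >= 1")
        if self.omega < 0:
            raise QACOError("omega must be >= 0")


@dataclass
class AntPath:
    """The realised tabu walk of one ant: an ordered, repeat-free node list."""

    ant_index: int
    nodes: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise QACOError("ant path revisits a node")

    @property
    def visited(self) -> frozenset[int]:
        return frozenset(self.nodes)

    def steps(self):
        return zip(self.nodes[:-1], self.nodes[1:])


# ---------------------------------------------------------------------------
# state initialisation


def init_pheromone(n: int, delta: float) -> np.ndarray:
    """Uniform pheromone δ on every node pair of the completion; zero diagonal."""
    if n < 2:
        raise QACOError("need at least 2 nodes")
    if delta <= 0:
        raise QACOError(f"delta must be positive, got {delta}")
    tau = np.full((n, n), float(delta))
    np.fill_diagonal(tau, 0.0)
    return tau


def compute_visibility(g: Graph, iota: int = 1, omega: float = 0.01) -> np.ndarray:
    """Quasi-local visibility η for every node pair.

    ``η_ij = Σ_{z ∈ Γ(i)∩Γ(j)} 1/k(z)^ι
           + ω · Σ_{simple paths i–x–y–j} 1/(k(x)·k(y))^ι``

    where the second sum runs over ordered intermediate pairs (x, y) of simple
    length-3 paths (x adjacent to i, y adjacent to j, x–y an edge, and
    x, y ∉ {i, j}, x ≠ y).  Computed densely for all pairs, adjacent ones
    included; symmetric with zero diagonal.
    """
    if iota not in (0, 1):
        raise QACOError(f"iota must be 0 or 1, got {iota}")
    if omega < 0:
        raise QACOError("omega must be >= 0")
    a = g.adjacency_matrix()
    k = a.sum(axis=1)
    if iota == 1:
        with np.errstate(divide="ignore"):
            w = np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), 0.0)
    else:
        w = np.ones_like(k)
    # common-neighbour term: Σ_z a[i,z]·w_z·a[z,j]
    cn = a @ (w[:, None] * a)
    # unconstrained 3-path term Σ_{x,y} a[i,x]w_x a[x,y] w_y a[y,j];
    # x=y vanishes (zero diagonal of a); subtract x=j and y=i by
    # inclusion-exclusion — both carry a factor a[i,j], so only adjacent
    # pairs are corrected.
    aw = a * w[None, :]
    t0 = aw @ a @ aw.T
    q = a @ w
    corr = a * (w * q)[None, :] + a * (w * q)[:, None] - a * np.outer(w, w)
    eta = cn + omega * (t0 - corr)
    np.fill_diagonal(eta, 0.0)
    return eta


def init_register(n: int, m: int) -> np.ndarray:
    """Per-node, per-ant qubits, all in the balanced state (1/√2, 1/√2).

    Shape (n, m, 2): ``reg[j, k] = (α_{j,k}, β_{j,k})``.
    """
    if n < 1 or m < 1:
        raise QACOError("need n >= 1 nodes and m >= 1 ants")
    return np.full((n, m, 2), INV_SQRT2)


# ---------------------------------------------------------------------------
# quantum pheromone


def quantum_intensity(reg: np.ndarray, node: int, ant: int) -> float:
    """Node attractiveness μ = 1/|α|², floored at |α|² = 1e-6."""
    alpha = reg[node, ant, 0]
    return 1.0 / max(alpha * alpha, ALPHA_SQ_FLOOR)


def _intensity_matrix(reg: np.ndarray) -> np.ndarray:
    """μ for every (node, ant) pair; shape (n, m)."""
    return 1.0 / np.maximum(reg[..., 0] ** 2, ALPHA_SQ_FLOOR)


def rotate_qubit(alpha, beta, dtheta):
    """Apply the quantum rotation gate by θ = Δθ·sign(α·β).

    The three-valued sign rule makes the basis states |0⟩ = (±1, 0) and
    |1⟩ = (0, ±1) fixed points; mixed states with α·β > 0 rotate toward |1⟩.
    Accepts scalars or broadcastable arrays; the norm α²+β² is preserved.
    """
    theta = dtheta * np.sign(np.asarray(alpha) * np.asarray(beta))
    c, s = np.cos(theta), np.sin(theta)
    return c * alpha - s * beta, s * alpha + c * beta


def update_register(reg: np.ndarray, paths: list[AntPath], dtheta: float) -> np.ndarray:
    """Rotate, for each ant k, the k-th qubit of every node on ant k's path.

    One rotation per visit; qubits of unvisited (node, ant) pairs are
    untouched.  Returns a new register.
    """
    out = reg.copy()
    for path in paths:
        k = path.ant_index
        idx = list(path.nodes)
        a, b = rotate_qubit(reg[idx, k, 0], reg[idx, k, 1], dtheta)
        out[idx, k, 0] = a
        out[idx, k, 1] = b
    return out


# ---------------------------------------------------------------------------
# walking


def _step_weights(current, visited, tau_lam, eta_kap, mu_nu_col):
    w = tau_lam[current] * eta_kap[current] * mu_nu_col
    w = np.where(visited, 0.0, w)
    return w


def _sample_index(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index proportional to ``weights`` (not all zero)."""
    c = np.cumsum(weights)
    total = c[-1]
    u = rng.random() * total
    idx = int(np.searchsorted(c, u, side="right"))
    if idx >= len(weights):  # u == total at float boundary
        idx = int(np.flatnonzero(weights)[-1])
    return idx


def _pow(base: np.ndarray, exponent: float) -> np.ndarray:
    # 0^0 := 1 (numpy's convention already); avoid copies for exponent 1
    if exponent == 1.0:
        return base
    return base ** exponent


def transition_distribution(
    current: int,
    tabu,
    tau: np.ndarray,
    eta: np.ndarray,
    reg: np.ndarray,
    ant: int,
    p: QACOParams,
):
    """Transition probabilities from ``current`` over the non-tabu nodes.

    Returns ``(candidates, probs)`` as parallel arrays; an empty candidate
    set signals walk termination.  Weight(j) = τ_ij^λ·η_ij^κ·μ_j^ν with
    0^0 = 1; when all weights vanish the distribution falls back to uniform
    over the candidates.
    """
    n = tau.shape[0]
    visited = np.zeros(n, dtype=bool)
    visited[list(tabu)] = True
    visited[current] = True
    candidates = np.flatnonzero(~visited)
    if candidates.size == 0:
        return candidates, np.empty(0)
    mu_nu = _pow(_intensity_matrix(reg)[:, ant], p.nu)
    w = _step_weights(current, visited, _pow(tau, p.lam), _pow(eta, p.kappa), mu_nu)
    w = w[candidates]
    total = w.sum()
    if total <= 0.0:
        probs = np.full(candidates.size, 1.0 / candidates.size)
    else:
        probs = w / total
    return candidates, probs


def walk_ant(
    start: int,
    steps: int,
    tau: np.ndarray,
    eta: np.ndarray,
    reg: np.ndarray,
    ant: int,
    p: QACOParams,
    rng: np.random.Generator,
) -> AntPath:
    """Tabu walk of one ant from ``start`` using frozen (τ, η, register).

    The path visits at most min(steps, n) nodes and never revisits a node;
    it ends early when no candidate remains.
    """
    if steps < 1:
        raise QACOError("steps must be >= 1")
    n = tau.shape[0]
    tau_lam = _pow(tau, p.lam)
    eta_kap = _pow(eta, p.kappa)
    mu_nu = _pow(_intensity_matrix(reg)[:, ant], p.nu)
    nodes = _walk(start, min(steps, n), tau_lam, eta_kap, mu_nu, rng)
    return AntPath(ant_index=ant, nodes=nodes)


def _walk(start, max_nodes, tau_lam, eta_kap, mu_nu, rng) -> tuple[int, ...]:
    n = tau_lam.shape[0]
    visited = np.zeros(n, dtype=bool)
    visited[start] = True
    nodes = [start]
    current = start
    while len(nodes) < max_nodes:
        w = _step_weights(current, visited, tau_lam, eta_kap, mu_nu)
        total = w.sum()
        if total <= 0.0:
            w = (~visited).astype(float)
            total = w.sum()
            if total <= 0.0:
                break
        nxt = _sample_index(w, rng)
        visited[nxt] = True
        nodes.append(nxt)
        current = nxt
    return tuple(nodes)


# ---------------------------------------------------------------------------
# fitness and pheromone dynamics


def path_fitness(path: AntPath, g: Graph, C: float = 1.0) -> float:
    """Q(S) = C · mean training-graph degree along the path."""
    if not path.nodes:
        raise QACOError("empty path has no fitness")
    deg = g.degrees()
    return C * float(np.mean(deg[list(path.nodes)]))


def update_pheromone(
    tau: np.ndarray,
    paths: list[AntPath],
    fitnesses: list[float],
    reg: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Decay every pair by ρ, then deposit along each ant's realised steps.

    The deposit of ant k on step (v_i → v_j) is ``Q_k·(1 − β_{j,k}²)`` with
    β taken from the register frozen at iteration start; deposits are applied
    symmetrically.  Returns a new matrix.
    """
    if len(paths) != len(fitnesses):
        raise QACOError("one fitness per path required")
    if not 0.0 <= rho < 1.0:
        raise QACOError(f"rho must be in [0,1), got {rho}")
    out = rho * tau
    for path, q in zip(paths, fitnesses):
        k = path.ant_index
        for i, j in path.steps():
            dep = q * (1.0 - reg[j, k, 1] ** 2)
            out[i, j] += dep
            out[j, i] += dep
    return out


# ---------------------------------------------------------------------------
# driver


def run_qaco(g: Graph, p: QACOParams | None = None) -> ScoreMatrix:
    """Run the full QACO loop on a training graph and assemble τ + ε·η.

    Each iteration: shuffle the node order and place the m ants on the first
    m nodes; let every ant walk (tabu, synchronous — all ants read the state
    frozen at iteration start); score each path by its mean degree; decay and
    reinforce τ; rotate the visited qubits.  Fully reproducible from p.seed.
    """
    p = p or QACOParams()
    p.validate()
    n = g.n_nodes
    if n < 3:
        raise QACOError("need at least 3 nodes")
    if p.n_ants > n:
        raise QACOError(f"n_ants={p.n_ants} exceeds node count {n}")
    rng = np.random.default_rng(p.seed)

    eta = compute_visibility(g, iota=p.iota, omega=p.omega)
    tau = init_pheromone(n, p.delta)
    reg = init_register(n, p.n_ants)
    steps = min(p.path_len if p.path_len is not None else n, n)
    eta_kap = _pow(eta, p.kappa)
    deg = g.degrees()

    for it in range(p.n_iter):
        tau_lam = _pow(tau, p.lam)
        mu_nu = _pow(_intensity_matrix(reg), p.nu)  # (n, m)
        starts = rng.permutation(n)[: p.n_ants]
        paths = []
        for k in range(p.n_ants):
            nodes = _walk(int(starts[k]), steps, tau_lam, eta_kap, mu_nu[:, k], rng)
            paths.append(AntPath(ant_index=k, nodes=nodes))
        fitnesses = [p.C * float(np.mean(deg[list(path.nodes)])) for path in paths]
        tau = update_pheromone(tau, paths, fitnesses, reg, p.rho)
        reg = update_register(reg, paths, p.dtheta)
        logger.debug(
            "iter %d: mean tau=%.4g max tau=%.4g norm drift=%.2e",
            it,
            tau.mean(),
            tau.max(),
            float(np.abs((reg ** 2).sum(-1) - 1.0).max()),
        )

    values = tau + p.eps * eta
    mask = candidate_mask_from_adjacency(g.adjacency_matrix())
    params = {f: getattr(p, f) for f in p.__dataclass_fields__}
    return ScoreMatrix(
        values=values,
        labels=g.labels,
        candidate_mask=mask,
        name="qaco",
        params=params,
    )
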