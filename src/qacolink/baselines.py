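"""Comparison link predictors: common neighbours, Cannistraci-Hebb, and the
structural perturbation method.

CN counts shared neighbours.  CH additionally asks whether those shared
neighbours form a dense local community: each common neighbour z contributes
the fraction of its own neighbours that are also common neighbours of the
pair.  SPM is model-free: it removes a random fraction of the training edges,
eigen-decomposes the remainder, restores the removed part through first-order
eigenvalue perturbation, and ranks non-observed pairs by the perturbed
reconstruction averaged over independent perturbation sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph import Graph, GraphError
from .scores import ScoreMatrix, candidate_mask_from_adjacency

logger = logging.getLogger(__name__)


def cn_score(g: Graph) -> ScoreMatrix:
    """Common-neighbour counts |Γ(x) ∩ Γ(y)| for all node pairs."""
    a = g.adjacency_matrix()
    values = a @ a
    np.fill_diagonal(values, 0.0)
    return ScoreMatrix(
        values=values,
        labels=g.labels,
        candidate_mask=candidate_mask_from_adjacency(a),
        name="cn",
    )


def ch_score(g: Graph) -> ScoreMatrix:
    """Cannistraci-Hebb index: Σ_{z∈Γ(x)∩Γ(y)} |γ(z)| / |Γ(z)|.

    γ(z) is the subset of z's neighbours that are themselves common
    neighbours of x and y (the local community degree of z).  A common
    neighbour is adjacent to x, so |Γ(z)| ≥ 1 and no division by zero can
    occur.  Pairs without common neighbours score 0.
    """
    n = g.n_nodes
    a = g.adjacency_matrix()
    cn_counts = a @ a
    nbrs = [g.neighbors(i) for i in range(n)]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if cn_counts[i, j] == 0:
                continue
            common = nbrs[i] & nbrs[j]
            s = sum(len(nbrs[z] & common) / len(nbrs[z]) for z in common)
            values[i, j] = values[j, i] = s
    return ScoreMatrix(
        values=values,
        labels=g.labels,
        candidate_mask=candidate_mask_from_adjacency(a),
        name="ch",
    )


@dataclass(frozen=True)
class SPMConfig:
    """Settings for the structural perturbation method.

    perturb_fraction is the share of training edges in each perturbation set
    ΔE; n_avg independent perturbation sets are averaged.
    """

    perturb_fraction: float = 0.1
    n_avg: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.perturb_fraction < 1.0:
            raise GraphError(
                f"perturb_fraction must be in [0,1), got {self.perturb_fraction}"
            )
        if self.n_avg < 1:
            raise GraphError("n_avg must be >= 1")


def spm_score(g: Graph, cfg: SPMConfig | None = None) -> ScoreMatrix:
    """Structural perturbation method score matrix.

    Per round: sample ΔE (round(perturb_fraction·|E|) edges), form
    A_R = A − ΔA, eigendecompose A_R = Σ λ_k x_k x_kᵀ, correct each
    eigenvalue to first order by Δλ_k = x_kᵀ·ΔA·x_k / x_kᵀ·x_k, and
    reconstruct Σ (λ_k + Δλ_k) x_k x_kᵀ.  Scores are the mean reconstruction
    over rounds, read on non-adjacent pairs.  With an empty perturbation set
    (fraction rounding to zero edges, exposed for testing) the reconstruction
    is the adjacency matrix itself up to eigensolver round-off.
    """
    cfg = cfg or SPMConfig()
    cfg.validate()
    n = g.n_nodes
    if n < 3:
        raise GraphError("SPM needs at least 3 nodes")
    edges = g.edges_idx()
    m = len(edges)
    n_remove = int(np.floor(cfg.perturb_fraction * m + 0.5))
    if m > 0 and n_remove >= m:
        raise GraphError("perturbation would remove all training edges")
    a = g.adjacency_matrix()
    rng = np.random.default_rng(cfg.seed)
    acc = np.zeros((n, n))
    for _ in range(cfg.n_avg):
        da = np.zeros((n, n))
        if n_remove > 0:
            picked = rng.choice(m, size=n_remove, replace=False)
            for e in picked:
                i, j = edges[e]
                da[i, j] = da[j, i] = 1.0
        ar = a - da
        lam, x = np.linalg.eigh(ar)
        gaps = np.diff(lam)
        if gaps.size and gaps.min() < 1e-8:
            logger.warning(
                "near-degenerate eigenvalues (min gap %.2e); first-order "
                "corrections applied per eigenvector as computed",
                float(gaps.min()),
            )
        # Δλ_k = x_kᵀ ΔA x_k / x_kᵀ x_k (normalisation kept for fidelity)
        dlam = ((x.T @ da) * x.T).sum(axis=1) / (x * x).sum(axis=0)
        acc += (x * (lam + dlam)) @ x.T
    values = acc / cfg.n_avg
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return ScoreMatrix(
        values=values,
        labels=g.labels,
        candidate_mask=candidate_mask_from_adjacency(a),
        name="spm",
        params={
            "perturb_fraction": cfg.perturb_fraction,
            "n_avg": cfg.n_avg,
            "seed": cfg.seed,
        },
    )
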