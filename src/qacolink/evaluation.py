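"""Precision protocols, predictor rankings, permutation tests, and the
time-evolving snapshot protocol.

A *predictor* throughout this module is a callable ``predictor(graph, seed)``
returning a :class:`~qacolink.scores.ScoreMatrix` trained on that graph
alone.  Deterministic predictors ignore the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .graph import Graph, GraphError, EdgeSplit, split_edges, training_graph
from .scores import ScoreMatrix

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# precision


def precision_at(scores: ScoreMatrix, split: EdgeSplit, L: int) -> float:
    """Precision = |top-L candidates ∩ probe| / L.

    Candidates are the pairs non-adjacent in the training graph (the score
    matrix's candidate mask); ranking is the deterministic score-descending,
    label-lexicographic order.
    """
    if L < 1:
        raise EvaluationError("L must be >= 1")
    if not split.probe:
        raise EvaluationError("probe set is empty")
    n_cand = scores.n_candidates
    if L > n_cand:
        raise EvaluationError(f"L={L} exceeds candidate count {n_cand}")
    idx = {lab: i for i, lab in enumerate(scores.labels)}
    probe_idx = set()
    for u, v in split.probe:
        i, j = idx[u], idx[v]
        probe_idx.add((min(i, j), max(i, j)))
    hits = 0
    for i, j in scores.ranked_candidates()[:L]:
        if (min(i, j), max(i, j)) in probe_idx:
            hits += 1
    return hits / L


@dataclass
class PrecisionResult:
    """Mean precision of one predictor on one network over repeated splits."""

    predictor: str
    network: str
    precisions: list[float]
    L: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.precisions))

    @property
    def stderr(self) -> float:
        if len(self.precisions) < 2:
            return 0.0
        return float(np.std(self.precisions, ddof=1) / math.sqrt(len(self.precisions)))


def evaluate_predictor(
    g: Graph,
    predictor,
    fraction: float = 0.9,
    n_splits: int = 100,
    seed: int = 0,
    predictor_name: str = "predictor",
    network_name: str = "network",
) -> PrecisionResult:
    """Repeated random train/probe evaluation.

    On each of ``n_splits`` independent splits the predictor is trained on
    the training edges only and scored with L = |E^P|.
    """
    if n_splits < 1:
        raise EvaluationError("n_splits must be >= 1")
    split_seeds = np.random.default_rng(seed).integers(0, 2 ** 31, size=n_splits)
    precisions = []
    L = None
    for s in split_seeds:
        split = split_edges(g, fraction, int(s))
        gt = training_graph(g, split)
        scores = predictor(gt, int(s))
        L = len(split.probe)
        precisions.append(precision_at(scores, split, L))
    return PrecisionResult(
        predictor=predictor_name, network=network_name, precisions=precisions, L=L
    )


# ---------------------------------------------------------------------------
# precision-ranking across networks


@dataclass
class RankingTable:
    """Per-network predictor ranks and their mean (the overall score).

    Rank 1 = highest precision within a network; ties share the midpoint
    rank, so fractional mean rankings (e.g. 4.5) can occur.
    """

    precisions: pd.DataFrame   # networks × predictors
    ranks: pd.DataFrame
    mean_ranking: pd.Series


def precision_ranking(table: pd.DataFrame) -> RankingTable:
    """Rank predictors within each network by precision, then average."""
    if table.isna().any().any():
        raise EvaluationError("precision table has missing cells")
    ranks = table.rank(axis=1, ascending=False, method="average")
    return RankingTable(
        precisions=table.copy(),
        ranks=ranks,
        mean_ranking=ranks.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# permutation tests


def permutation_test_rankings(col_a, col_b, n_iter: int = 10000, seed: int = 0) -> float:
    """Paired sign-flip permutation test on two rank columns.

    The statistic is |mean(a) − mean(b)|; the null swaps each network's pair
    of ranks independently with probability 1/2.  Two-sided p-value with the
    add-one correction (1 + #{null ≥ observed}) / (1 + n_iter).
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise EvaluationError("rank columns must be equal-length 1-D")
    if n_iter < 1:
        raise EvaluationError("n_iter must be >= 1")
    d = a - b
    observed = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iter, d.size))
    null = np.abs((signs * d).mean(axis=1))
    exceed = int(np.sum(null >= observed - 1e-12))
    return (1 + exceed) / (1 + n_iter)


def pairwise_permutation_tests(
    ranks: pd.DataFrame, n_iter: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """All pairwise rank comparisons, Benjamini-Hochberg adjusted.

    Returns a long-format frame (predictor_a, predictor_b, p_value, p_adjusted).
    """
    cols = list(ranks.columns)
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            p = permutation_test_rankings(
                ranks[cols[i]].to_numpy(),
                ranks[cols[j]].to_numpy(),
                n_iter=n_iter,
                seed=int(rng.integers(0, 2 ** 31)),
            )
            rows.append({"predictor_a": cols[i], "predictor_b": cols[j], "p_value": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# time-evolving protocol


@dataclass
class SnapshotSeries:
    """Ordered network snapshots with strictly increasing time labels."""

    times: list
    graphs: list

    def __post_init__(self):
        if len(self.times) != len(self.graphs):
            raise EvaluationError("times and graphs must align")
        if len(self.graphs) < 2:
            raise EvaluationError("need at least 2 snapshots")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise EvaluationError("time labels must be strictly increasing")


def evaluate_time_series(series: SnapshotSeries, predictor, seed: int = 0):
    """Top-r precision for every ordered snapshot pair (i, j), i < j.

    For each pair, candidates are the node pairs non-adjacent at time i whose
    endpoints both still exist at time j; r is the number of candidates that
    are edges at time j.  Precision(i, j) = |top-r ∩ edges(j)| / r.  Cells
    with r = 0 are skipped with a warning, and the reported mean covers only
    defined cells.

    Returns ``(cells, mean)`` where cells maps (i, j) index pairs to
    precision.
    """
    n_snap = len(series.graphs)
    rng = np.random.default_rng(seed)
    cells: dict[tuple[int, int], float] = {}
    for i in range(n_snap):
        gi = series.graphs[i]
        scores = predictor(gi, int(rng.integers(0, 2 ** 31)))
        idx = {lab: k for k, lab in enumerate(scores.labels)}
        ranked = scores.ranked_candidates()
        for j in range(i + 1, n_snap):
            gj = series.graphs[j]
            alive = set(gj.labels)
            future_edges = gj.edge_labels()

            def pair_labels(a, b):
                u, v = gi.labels[a], gi.labels[b]
                return (u, v) if u <= v else (v, u)

            candidates = [
                (a, b)
                for a, b in ranked
                if gi.labels[a] in alive and gi.labels[b] in alive
            ]
            r = sum(1 for a, b in candidates if pair_labels(a, b) in future_edges)
            if r == 0:
                logger.warning(
                    "snapshot pair (%s, %s): no appearing links; cell skipped",
                    series.times[i],
                    series.times[j],
                )
                continue
            hits = sum(
                1 for a, b in candidates[:r] if pair_labels(a, b) in future_edges
            )
            cells[(i, j)] = hits / r
    mean = float(np.mean(list(cells.values()))) if cells else float("nan")
    return cells, mean


# ---------------------------------------------------------------------------
# report writers


def write_long_table(path, results: list[PrecisionResult]) -> None:
    """Long-format TSV: network, predictor, split, precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("network\tpredictor\tsplit\tprecision\n")
        for r in results:
            for s, p in enumerate(r.precisions):
                fh.write(f"{r.network}\t{r.predictor}\t{s}\t{p:.10g}\n")


def summary_table(results: list[PrecisionResult]) -> pd.DataFrame:
    """Networks × predictors mean-precision table."""
    df = pd.DataFrame(
        [
            {"network": r.network, "predictor": r.predictor, "mean": r.mean}
            for r in results
        ]
    )
    return df.pivot(index="network", columns="predictor", values="mean")
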