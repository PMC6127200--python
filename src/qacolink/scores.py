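"""Score matrices over candidate (disconnected) node pairs.

Every predictor in this package returns a :class:`ScoreMatrix`: a symmetric
n×n array of likelihood scores together with the candidate mask — the node
pairs that are non-adjacent in the graph the predictor was trained on.
Ranking is deterministic: descending score, ties broken by the
lexicographically smallest (label-sorted) node pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScoreMatrix:
    values: np.ndarray            # symmetric n×n, finite
    labels: tuple[str, ...]       # index -> label
    candidate_mask: np.ndarray    # boolean n×n; True where pair is a candidate
    name: str = "score"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.labels)
        if self.values.shape != (n, n) or self.candidate_mask.shape != (n, n):
            raise ValueError("matrix shape does not match label count")

    @property
    def n_candidates(self) -> int:
        return int(np.triu(self.candidate_mask, 1).sum())

    def ranked_candidates(self) -> list[tuple[int, int]]:
        """Candidate index pairs sorted by (score desc, label pair lex asc)."""
        iu, ju = np.nonzero(np.triu(self.candidate_mask, 1))
        vals = self.values[iu, ju]
        lab = np.asarray(self.labels, dtype=str)
        u, v = lab[iu], lab[ju]
        swap = v < u
        lo = np.where(swap, v, u)
        hi = np.where(swap, u, v)
        order = np.lexsort((hi, lo, -vals))
        return list(zip(iu[order].tolist(), ju[order].tolist()))

    def ranked_label_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for i, j in self.ranked_candidates():
            u, v = self.labels[i], self.labels[j]
            if v < u:
                u, v = v, u
            out.append((u, v, float(self.values[i, j])))
        return out

    def to_tsv(self, path) -> None:
        """Write the ranked candidate list as tab-separated text.

        Header lines echo the predictor name and parameters so a run can be
        replayed; rows are ``node_u<TAB>node_v<TAB>score`` in rank order.
        """
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# predictor={self.name}\n")
            for key in sorted(self.params):
                fh.write(f"# {key}={self.params[key]}\n")
            fh.write("# node_u\tnode_v\tscore\n")
            for u, v, s in self.ranked_label_pairs():
                fh.write(f"{u}\t{v}\t{s:.17g}\n")


def candidate_mask_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Candidates = non-adjacent, non-identical pairs of the training graph."""
    mask = a == 0
    np.fill_diagonal(mask, False)
    return mask
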