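"""Signature comparison by RMSD and per-compound ranked similarity lists.

Two proteome interaction signatures are compared by root-mean-squared
deviation over the proteome; the all-pairs RMSDs form a symmetric
compound-compound similarity matrix with zero diagonal.  Sorting a
query's row ascending (small RMSD = similar) yields its ranked list of
the other N−1 compounds — the object the leave-one-out benchmark
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .scoring import InteractionMatrix

__all__ = [
    "SimilarityMatrix",
    "RankedList",
    "RankEntry",
    "signature_rmsd",
    "compound_similarity_matrix",
    "ranked_list",
    "all_ranked_lists",
]


def signature_rmsd(a: Sequence[float], b: Sequence[float]) -> float:
    """sqrt(mean((a_i − b_i)²)) over the proteome; vectors must match in length."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError(f"signature length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class SimilarityMatrix:
    """All-pairs signature RMSDs: symmetric, zero diagonal, non-negative."""

    compound_ids: list
    rmsd: np.ndarray

    def __post_init__(self) -> None:
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        n = len(self.compound_ids)
        if self.rmsd.shape != (n, n):
            raise ValueError("RMSD matrix shape does not match compound ids")

    def value(self, a: str, b: str) -> float:
        i = self.compound_ids.index(a)
        j = self.compound_ids.index(b)
        return float(self.rmsd[i, j])


class RankEntry(NamedTuple):
    rank: int
    compound_id: str
    rmsd: float


@dataclass
class RankedList:
    """One compound's neighbours sorted by ascending RMSD, self excluded.

    Ranks are 1-based and gap-free; ties in RMSD are broken
    lexicographically by compound id so lists are reproducible.
    """

    query_compound_id: str
    entries: list

    def top(self, k: int) -> list:
        return self.entries[:k]

    def rank_of(self, compound_id: str) -> int:
        for e in self.entries:
            if e.compound_id == compound_id:
                return e.rank
        raise KeyError(compound_id)


def compound_similarity_matrix(matrix: InteractionMatrix) -> SimilarityMatrix:
    """RMSD between every pair of proteome interaction signatures."""
    if matrix.n_compounds < 2:
        raise ValueError("similarity matrix needs at least 2 compounds")
    # pairwise Euclidean / sqrt(P) == root-mean-squared deviation
    d = squareform(pdist(matrix.scores, metric="euclidean"))
    d /= np.sqrt(matrix.n_proteins)
    return SimilarityMatrix(compound_ids=list(matrix.compound_ids), rmsd=d)


def ranked_list(sim: SimilarityMatrix, query: str) -> RankedList:
    """Rank all other compounds by ascending RMSD to the query."""
    try:
        qi = sim.compound_ids.index(query)
    except ValueError:
        raise KeyError(f"unknown query compound {query!r}") from None
    pairs = [
        (float(sim.rmsd[qi, j]), cid)
        for j, cid in enumerate(sim.compound_ids)
        if j != qi
    ]
    pairs.sort()  # (rmsd, id): ascending RMSD, lexicographic id tie-break
    entries = [RankEntry(r, cid, v) for r, (v, cid) in enumerate(pairs, start=1)]
    return RankedList(query_compound_id=query, entries=entries)


def all_ranked_lists(sim: SimilarityMatrix) -> Dict[str, RankedList]:
    """Ranked list for every compound, keyed by query id."""
    return {cid: ranked_list(sim, cid) for cid in sim.compound_ids}
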