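"""Similarity metrics, Savage scores, and the distance-weighted kNN vote.

Six metrics are supported: Pearson, Spearman and Kendall correlations,
cosine similarity, Jaccard similarity of binarized vectors, and weighted
rank correlation (Pearson correlation of Savage scores, the Iman-Conover
top-down correlation). All are expressed as similarities; the distance
used by the kNN machinery is uniformly ``d = 1 - s``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

METRICS = ("pearson", "spearman", "kendall", "cosine", "jaccard", "weighted_rank")


def savage_scores(n: int) -> np.ndarray:
    """Savage (expected exponential order statistic) scores.

    The score for rank ``r`` (rank 1 = largest value) is
    ``sum_{i=r}^{n} 1/i``; the scores sum to ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    inv = 1.0 / np.arange(1, n + 1)
    return np.cumsum(inv[::-1])[::-1]


def _rank_rows(X: np.ndarray) -> np.ndarray:
    # average ranks, ascending; constant rows give constant ranks
    return np.apply_along_axis(rankdata, 1, X)


def _savage_rows(X: np.ndarray) -> np.ndarray:
    """Savage-score transform of each row, averaging scores over tie groups."""
    n = X.shape[1]
    scores = savage_scores(n)  # index 0 = rank 1 = largest
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    out = np.empty_like(X, dtype=float)
    for i, row in enumerate(X):
        order = np.argsort(-row, kind="stable")
        sorted_vals = row[order]
        # boundaries of tie groups in the sorted (descending) order
        starts = np.flatnonzero(
            np.concatenate([[True], sorted_vals[1:] != sorted_vals[:-1]])
        )
        ends = np.concatenate([starts[1:], [n]])
        assigned = np.empty(n)
        for a, b in zip(starts, ends):
            assigned[a:b] = (csum[b] - csum[a]) / (b - a)
        out[i, order] = assigned
    return out


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit norm; constant rows become all-zero."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    np.divide(Xc, norms, out=Xc, where=norms > 0)
    Xc[np.squeeze(norms, axis=1) == 0] = 0.0
    return Xc


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    out = np.divide(X, norms, out=np.zeros_like(X, dtype=float), where=norms > 0)
    return out


def _pair_signs(X: np.ndarray) -> np.ndarray:
    """Sign of all pairwise within-row differences, rows x n*(n-1)/2."""
    n = X.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return np.sign(X[:, iu] - X[:, ju]).astype(np.float32)


def pairwise_similarity(
    Q: np.ndarray,
    R: np.ndarray,
    metric: str,
    jaccard_threshold: float = 0.0,
) -> np.ndarray:
    """Similarity between every row of ``Q`` and every row of ``R``.

    Rows are cells, columns genes. Correlation-type metrics return 0
    for zero-variance vectors; Jaccard of two empty supports is 1.
    Kendall uses the tau-b tie correction, computed as the cosine of
    the pairwise-difference sign vectors.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if Q.shape[1] != R.shape[1]:
        raise ValueError("query and reference must have the same gene dimension")
    if Q.shape[1] < 2:
        raise ValueError("similarity requires vectors of length >= 2")

    if metric == "pearson":
        return _standardize_rows(Q) @ _standardize_rows(R).T
    if metric == "spearman":
        return _standardize_rows(_rank_rows(Q)) @ _standardize_rows(_rank_rows(R)).T
    if metric == "weighted_rank":
        return _standardize_rows(_savage_rows(Q)) @ _standardize_rows(_savage_rows(R)).T
    if metric == "cosine":
        return _unit_rows(Q) @ _unit_rows(R).T
    if metric == "kendall":
        # tau-b = <sq, sr> / (|sq| |sr|) over pairwise-difference signs,
        # which counts concordant minus discordant pairs with tie correction
        sq = _pair_signs(Q)
        sr = _pair_signs(R)
        num = sq @ sr.T
        nq = np.linalg.norm(sq, axis=1, keepdims=True)
        nr = np.linalg.norm(sr, axis=1, keepdims=True)
        denom = nq @ nr.T
        out = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
        return out.astype(float)
    if metric == "jaccard":
        Bq = (Q > jaccard_threshold).astype(np.float64)
        Br = (R > jaccard_threshold).astype(np.float64)
        inter = Bq @ Br.T
        union = Bq.sum(axis=1, keepdims=True) + Br.sum(axis=1)[np.newaxis, :] - inter
        out = np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)
        out[union == 0] = 1.0  # two empty supports are identical
        return out
    raise ValueError(f"unknown metric {metric!r}")


def similarity(
    x: np.ndarray, y: np.ndarray, metric: str, jaccard_threshold: float = 0.0
) -> float:
    """Similarity between two vectors under one of the six metrics."""
    return float(
        pairwise_similarity(
            np.asarray(x)[np.newaxis, :],
            np.asarray(y)[np.newaxis, :],
            metric,
            jaccard_threshold,
        )[0, 0]
    )


@dataclass
class NeighborSet:
    """K nearest reference cells for one query cell, sorted by distance."""

    neighbor_ids: list[str]
    distances: np.ndarray  # ascending
    similarities: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.similarities = np.asarray(self.similarities, dtype=float)
        if len(self.distances) < 1:
            raise ValueError("a NeighborSet needs at least one neighbour")
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be sorted ascending")
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("distances must be finite")


def nearest_indices(distances: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest distances; ties broken by reference order."""
    # stable sort on distance keeps original index order among ties
    order = np.argsort(distances, kind="stable")
    return order[:k]


def knn_query(
    reference_values: np.ndarray,
    reference_ids: list[str],
    labels: np.ndarray,
    query: np.ndarray,
    k: int = 10,
    metric: str = "pearson",
    jaccard_threshold: float = 0.0,
) -> NeighborSet:
    """Exact exhaustive kNN of one query cell against a reference.

    ``reference_values`` is cells x genes (already restricted to the
    node's selected genes); ``query`` is a gene vector.
    """
    n = reference_values.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds reference size {n}")
    sims = pairwise_similarity(
        query[np.newaxis, :], reference_values, metric, jaccard_threshold
    )[0]
    dists = 1.0 - sims
    idx = nearest_indices(dists, k)
    return NeighborSet(
        neighbor_ids=[reference_ids[i] for i in idx],
        distances=dists[idx],
        similarities=sims[idx],
        labels=np.asarray(labels, dtype=object)[idx],
    )


def knn_weights(distances: np.ndarray) -> np.ndarray:
    """Dudani distance weights: w_k = (d_K - d_k) / (d_K - d_1).

    When all K distances are equal every weight is 1.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) < 1:
        raise ValueError("distances must be a non-empty 1-D array")
    dK, d1 = d[-1], d[0]
    if dK == d1:
        return np.ones_like(d)
    return (dK - d) / (dK - d1)


@dataclass
class VoteResult:
    """Outcome of a weighted majority vote over neighbour labels."""

    winner: str | None  # None on an exact tie
    winner_weight_share: float
    max_neighbor_similarity: float
    label_weights: dict[str, float]


def weighted_vote(neighbors: NeighborSet, weights: np.ndarray) -> VoteResult:
    """Weighted majority vote; an exact tie for the top label yields no winner."""
    weights = np.asarray(weights, dtype=float)
    totals: dict[str, float] = {}
    for lab, w in zip(neighbors.labels, weights):
        totals[lab] = totals.get(lab, 0.0) + float(w)
    total = sum(totals.values())
    best = max(totals.values())
    winners = sorted(lab for lab, w in totals.items() if w == best)
    if len(winners) > 1:
        winner = None
        share = best / total if total > 0 else 0.0
    else:
        winner = winners[0]
        share = best / total if total > 0 else 1.0
    return VoteResult(
        winner=winner,
        winner_weight_share=share,
        max_neighbor_similarity=float(np.max(neighbors.similarities)),
        label_weights=totals,
    )
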