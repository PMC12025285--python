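"""KNN hypergraphs over subjects and their normalized Laplacians.

A hypergraph joins two or more vertices per hyperedge and therefore captures
higher-order neighbourhood structure among subjects that a pairwise graph
loses.  Here every subject is a vertex; one hyperedge is centred on each
subject and contains that subject plus its ``k`` nearest neighbours in
feature space (Euclidean distance), so a cohort of ``N`` subjects yields
exactly ``N`` hyperedges, all of unit weight.

The normalized hypergraph Laplacian

    ``L_h = I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}``

is symmetric positive semidefinite; its quadratic form penalizes prediction
scores that disagree among co-members of a hyperedge, which is how it enters
the feature-selection objective as a regularizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Hypergraph",
    "HypergraphLaplacian",
    "build_knn_hypergraph",
    "laplacian",
    "quadratic_form",
]


@dataclass(frozen=True)
class Hypergraph:
    """Incidence structure of one hypergraph.

    Attributes
    ----------
    incidence : ndarray of shape (N, Ne)
        Binary vertex x hyperedge membership matrix ``H``.
    edge_weights : ndarray of shape (Ne,)
        Non-negative hyperedge weights ``w(e)``.
    vertex_degrees : ndarray of shape (N,)
        ``d(v) = sum_e w(e) H(v, e)``.
    edge_degrees : ndarray of shape (Ne,)
        ``delta(e) = sum_v H(v, e)`` (number of member vertices).
    """

    incidence: np.ndarray
    edge_weights: np.ndarray
    vertex_degrees: np.ndarray
    edge_degrees: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.incidence)
        if not np.isin(H, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        if (self.edge_weights < 0).any():
            raise ValueError("edge weights must be non-negative")
        if not np.array_equal(H.sum(axis=0), self.edge_degrees):
            raise ValueError("edge_degrees inconsistent with incidence")
        if not np.allclose(H @ self.edge_weights, self.vertex_degrees):
            raise ValueError("vertex_degrees inconsistent with incidence")
        if (self.edge_degrees <= 0).any():
            raise ValueError("empty hyperedge")
        if (self.vertex_degrees <= 0).any():
            raise ValueError("isolated vertex")

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]


@dataclass(frozen=True)
class HypergraphLaplacian:
    """Normalized hypergraph Laplacian ``L_h = I - Theta`` (symmetric PSD)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.matrix)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("Laplacian must be square")
        if not np.allclose(L, L.T, atol=1e-10):
            raise ValueError("Laplacian must be symmetric")


def build_knn_hypergraph(features: np.ndarray, k: int) -> Hypergraph:
    """Build the KNN hypergraph of a subject x feature matrix.

    One hyperedge per subject: the centre plus its ``k`` nearest neighbours
    by Euclidean distance.  Distance ties are broken toward the lower vertex
    index so builds are deterministic; duplicate subjects (zero distance) are
    allowed and the centre always ranks first in its own edge.  All hyperedge
    weights are 1.

    Parameters
    ----------
    features : ndarray of shape (N, d)
        Finite feature matrix.  Callers who want scale-free neighbourhoods
        should z-score columns first (the solver does this internally).
    k : int
        Number of neighbours per centre; requires ``N >= k + 1``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be a positive integer")
    if n <= k:
        raise ValueError("k exceeds available neighbors")

    # Pairwise squared Euclidean distances; exact ordering only matters up
    # to ties, which lexsort resolves toward the lower index.
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)  # self always ranks first

    H = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, d2[i]))  # distance asc, then index asc
        members = order[: k + 1]  # order[0] == i by the -inf diagonal
        H[members, i] = 1

    edge_weights = np.ones(n)
    edge_degrees = H.sum(axis=0)
    vertex_degrees = (H @ edge_weights).astype(float)
    return Hypergraph(H, edge_weights, vertex_degrees, edge_degrees)


def laplacian(hg: Hypergraph) -> HypergraphLaplacian:
    """Normalized Laplacian ``I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}``."""
    if (hg.vertex_degrees <= 0).any():
        raise ValueError("isolated vertex")
    H = hg.incidence.astype(float)
    dv_isqrt = 1.0 / np.sqrt(hg.vertex_degrees)
    # Theta = Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}, kept dense: cohorts are
    # at most a few thousand subjects.
    HW = H * (hg.edge_weights / hg.edge_degrees)
    theta = (dv_isqrt[:, None] * HW) @ (H.T * dv_isqrt[None, :])
    L = np.eye(hg.n_vertices) - theta
    L = 0.5 * (L + L.T)  # kill round-off asymmetry
    return HypergraphLaplacian(L)


def quadratic_form(lap: HypergraphLaplacian, scores: np.ndarray) -> float:
    """Evaluate ``scores^T L_h scores`` (the hypergraph smoothness penalty).

    Non-negative up to round-off; zero exactly on the null direction
    ``Dv^{1/2} 1``.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if s.shape[0] != lap.matrix.shape[0]:
        raise ValueError("dimension mismatch between Laplacian and scores")
    return float(s @ lap.matrix @ s)
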