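"""Executable illustration of the densest-k-subgraph reduction.

Searching for substructures under an RMSD bound with indels becomes NP-hard
when the dimension is unbounded.  The reduction realizes a graph G on n
vertices as a *two-distance point set* in n-1 dimensions: pairwise distance
alpha between adjacent vertices and beta between non-adjacent ones, with
0 < alpha < beta < 2*alpha.  Comparing a k-subset of those points against k
copies of the origin needs no rotation (the all-zero structure is
rotation-invariant) and only the centroid translation, which collapses the
RMSD to a closed form in the number x of edges induced by the subset:

    RMSD = sqrt(alpha^2 * x + beta^2 * (C(k,2) - x)) / k.

Since alpha < beta, minimizing the RMSD over k-subsets is exactly
maximizing x — i.e. solving densest k-subgraph.  This module embeds small
graphs by classical multidimensional scaling, verifies the two-distance
property, and demonstrates the equivalence exhaustively (n <= 14 enforced;
this is a demonstration, not a solver).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .core_geometry import Chain, rmsd

__all__ = [
    "GraphInstance",
    "TwoDistanceEmbedding",
    "NotEmbeddableError",
    "embed_graph",
    "subset_rmsd",
    "subset_rmsd_closed_form",
    "densest_k_subgraph_via_rmsd",
    "max_induced_edges",
]

MAX_DEMO_VERTICES = 14


class NotEmbeddableError(ValueError):
    """The requested two-distance point set has no Euclidean realization."""


@dataclass(frozen=True)
class GraphInstance:
    """A simple graph (0-based vertices) with a subset size k < n."""

    n: int
    edges: frozenset[tuple[int, int]]
    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.k < self.n:
            raise ValueError(f"subset size must satisfy 1 <= k < n, got k={self.k}, n={self.n}")
        norm = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u}, {v}) outside vertex range")
            norm.add((min(u, v), max(u, v)))
        object.__setattr__(self, "edges", frozenset(norm))

    @classmethod
    def from_networkx(cls, g: nx.Graph, k: int) -> "GraphInstance":
        nodes = sorted(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        edges = frozenset((index[u], index[v]) for u, v in g.edges())
        return cls(n=len(nodes), edges=edges, k=k)

    def has_edge(self, u: int, v: int) -> bool:
        return (min(u, v), max(u, v)) in self.edges

    def induced_edges(self, subset: Iterable[int]) -> int:
        vs = list(subset)
        return sum(1 for u, v in combinations(vs, 2) if self.has_edge(u, v))


@dataclass(frozen=True)
class TwoDistanceEmbedding:
    """Points in n-1 dimensions realizing a graph as a two-distance set."""

    points: np.ndarray  # (n, n-1)
    alpha: float
    beta: float

    def max_distance_error(self, g: GraphInstance) -> float:
        """Largest deviation of any pairwise distance from its alpha/beta target."""
        err = 0.0
        for u, v in combinations(range(g.n), 2):
            target = self.alpha if g.has_edge(u, v) else self.beta
            err = max(err, abs(float(np.linalg.norm(self.points[u] - self.points[v])) - target))
        return err


def embed_graph(
    g: GraphInstance, alpha: float = 1.0, beta: float = 1.05, psd_tol: float = 1e-9
) -> TwoDistanceEmbedding:
    """Two-distance realization of a graph by classical MDS.

    Builds the squared-distance matrix (alpha^2 on edges, beta^2 on
    non-edges), double-centers it to the Gram matrix B = -J D2 J / 2, and
    takes eigenvector coordinates scaled by sqrt(eigenvalue).  B must be
    positive semidefinite for the realization to exist; if its smallest
    eigenvalue is below ``-psd_tol`` (relative to the largest) a
    :class:`NotEmbeddableError` names it.
    """
    if not 0 < alpha < beta < 2 * alpha:
        raise ValueError(f"need 0 < alpha < beta < 2*alpha, got alpha={alpha}, beta={beta}")
    n = g.n
    D2 = np.full((n, n), beta * beta)
    np.fill_diagonal(D2, 0.0)
    for u, v in g.edges:
        D2[u, v] = D2[v, u] = alpha * alpha
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    scale = max(eigvals.max(), 1.0)
    if eigvals.min() < -psd_tol * scale:
        raise NotEmbeddableError(
            f"Gram matrix not positive semidefinite (smallest eigenvalue {eigvals.min():.3e}); "
            f"no Euclidean two-distance realization with alpha={alpha}, beta={beta}"
        )
    lam = np.clip(eigvals, 0.0, None)
    coords = eigvecs * np.sqrt(lam)[None, :]
    # keep exactly n-1 coordinates (one eigenvalue of B is always ~0 along 1)
    order = np.argsort(lam)[::-1][: n - 1]
    points = coords[:, order]
    return TwoDistanceEmbedding(points=points, alpha=alpha, beta=beta)


def subset_rmsd(emb: TwoDistanceEmbedding, subset: Sequence[int]) -> float:
    """RMSD between a vertex subset's points and as many zero vectors.

    Computed through the general superposition routine in dimension n-1;
    agrees with :func:`subset_rmsd_closed_form` because the zero structure
    is rotation-invariant and the optimal translation centers the subset.
    """
    idx = sorted(subset)
    if not idx:
        raise ValueError("subset must be non-empty")
    pts = emb.points[idx]
    zeros = np.zeros_like(pts)
    return rmsd(Chain(pts), Chain(zeros))


def subset_rmsd_closed_form(alpha: float, beta: float, k: int, x: int) -> float:
    """Closed form of the subset RMSD from the induced edge count x.

    Derivation: with Q the k zero vectors, only the centroid translation
    matters, so k * RMSD^2 = sum_i |p_i - G|^2, and the centroid identity
    sum_i |p_i - G|^2 = (1/k) * sum_{i<j} |p_i - p_j|^2 turns the pairwise
    two-distance structure into alpha^2 * x + beta^2 * (C(k,2) - x), giving
    RMSD = sqrt(alpha^2 x + beta^2 (C(k,2) - x)) / k.  Decreasing in x
    since alpha < beta.
    """
    if k < 1:
        raise ValueError("subset size must be >= 1")
    pairs = comb(k, 2)
    if not 0 <= x <= pairs:
        raise ValueError(f"edge count x={x} impossible for a subset of size {k}")
    return sqrt(alpha * alpha * x + beta * beta * (pairs - x)) / k


def densest_k_subgraph_via_rmsd(
    g: GraphInstance, alpha: float = 1.0, beta: float = 1.05
) -> tuple[int, ...]:
    """Densest k-subgraph solved through the geometric reduction.

    Embeds the graph, scans all C(n, k) subsets and returns the one whose
    point set has minimum RMSD to the zero structure — which, by the closed
    form above, induces the maximum number of edges.  Exhaustive
    demonstration only: n <= 14 enforced.
    """
    if g.n > MAX_DEMO_VERTICES:
        raise ValueError(f"demonstration limited to n <= {MAX_DEMO_VERTICES} vertices")
    emb = embed_graph(g, alpha, beta)
    best_subset: tuple[int, ...] | None = None
    best_val = np.inf
    for subset in combinations(range(g.n), g.k):
        val = subset_rmsd(emb, subset)
        if val < best_val:
            best_val = val
            best_subset = subset
    assert best_subset is not None
    return best_subset


def max_induced_edges(g: GraphInstance) -> int:
    """Brute-force densest-k-subgraph optimum (independent of any geometry)."""
    if g.n > MAX_DEMO_VERTICES:
        raise ValueError(f"demonstration limited to n <= {MAX_DEMO_VERTICES} vertices")
    return max(g.induced_edges(subset) for subset in combinations(range(g.n), g.k))
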