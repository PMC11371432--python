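"""Weighted Vietoris-Rips complexes over agent point clouds.

A Vietoris-Rips complex at filtration radius r contains every simplex whose
vertices are pairwise within distance r (inclusive).  The swarm is embedded
as a whole: every pair of agents closer than r contributes an edge, even
pairs closer than the interaction annulus' inner radius -- non-locality
restricts neighbour *candidacy* in the dynamics, not complex membership.

Weights follow the degree-based scheme used by the dynamics:

    w_i  = 1 + degree(i)
    w_ij = (w_i + w_j) / (1 + r_ij)

so hubs are heavy and long edges are light.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Box, pairwise_distances

__all__ = [
    "SimplicialComplex",
    "WeightAssignment",
    "build_rips",
    "complex_from_distance_matrix",
    "assign_weights",
    "degree_sequence",
]


@dataclass
class SimplicialComplex:
    """Simplicial complex up to dimension 2 with per-edge metric lengths.

    Edges are pairs (i, j) with i < j in lexicographic order; triangles,
    when present, are triples (i, j, k) with i < j < k, also lexicographic.
    ``edge_distances`` aligns with ``edges``.
    """

    n_vertices: int
    edges: np.ndarray  # (E, 2) int
    edge_distances: np.ndarray  # (E,) float
    filtration_radius: float
    max_dim: int = 1
    triangles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.intp))

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        self.triangles = np.asarray(self.triangles, dtype=np.intp).reshape(-1, 3)
        self.edge_distances = np.asarray(self.edge_distances, dtype=float).reshape(-1)
        if self.edge_distances.shape[0] != self.edges.shape[0]:
            raise ValueError("edge_distances must align with the edge list")
        if self.max_dim not in (1, 2):
            raise ValueError(f"max_dim must be 1 or 2, got {self.max_dim}")
        if self.edges.shape[0]:
            if self.edges.min() < 0 or self.edges.max() >= self.n_vertices:
                raise ValueError("edge indices out of range")
            if np.any(self.edges[:, 0] >= self.edges[:, 1]):
                raise ValueError("edges must satisfy i < j")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])

    def edge_index(self) -> dict[tuple[int, int], int]:
        """Map (i, j) -> position in the edge list."""
        return {(int(i), int(j)): e for e, (i, j) in enumerate(self.edges)}


@dataclass
class WeightAssignment:
    """Vertex and edge weights aligned with a complex's vertex/edge order."""

    vertex_weights: np.ndarray  # (V,) float, = 1 + degree
    edge_weights: np.ndarray  # (E,) float


def complex_from_distance_matrix(
    dist: np.ndarray,
    r: float,
    max_dim: int = 1,
    exclude_below: float | None = None,
) -> SimplicialComplex:
    """Rips complex from a precomputed symmetric distance matrix.

    ``exclude_below`` optionally drops edges strictly shorter than a cutoff
    (sensitivity-analysis knob; the default keeps every edge <= r).
    """
    if r <= 0:
        raise ValueError(f"filtration radius must be positive, got {r}")
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    keep = d <= r
    if exclude_below is not None:
        keep &= d >= exclude_below
    edges = np.column_stack([iu[keep], ju[keep]]).astype(np.intp)
    edge_d = d[keep]
    # np.triu_indices enumerates pairs in lexicographic (i, j) order already.
    cx = SimplicialComplex(
        n_vertices=n,
        edges=edges,
        edge_distances=edge_d,
        filtration_radius=float(r),
        max_dim=max_dim,
    )
    if max_dim == 2:
        cx.triangles = _fill_triangles(n, dist, r, edges)
    return cx


def _fill_triangles(n: int, dist: np.ndarray, r: float, edges: np.ndarray) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    if edges.shape[0]:
        adj[edges[:, 0], edges[:, 1]] = True
        adj[edges[:, 1], edges[:, 0]] = True
    tris = []
    for i, j in edges:
        # third vertex k > j keeps (i, j, k) lexicographic and unique
        ks = np.nonzero(adj[i] & adj[j])[0]
        for k in ks[ks > j]:
            tris.append((i, j, k))
    if not tris:
        return np.empty((0, 3), dtype=np.intp)
    out = np.array(sorted(tris), dtype=np.intp)
    return out


def build_rips(
    positions: np.ndarray,
    box: Box,
    r: float,
    max_dim: int = 1,
    exclude_below: float | None = None,
) -> SimplicialComplex:
    """Vietoris-Rips complex of a point cloud under periodic boundaries.

    Edges are all pairs at minimum-image distance <= r; with ``max_dim=2``,
    triangles are all triples whose three edges are present.
    """
    dist = pairwise_distances(positions, box)
    return complex_from_distance_matrix(dist, r, max_dim=max_dim, exclude_below=exclude_below)


def degree_sequence(cx: SimplicialComplex) -> np.ndarray:
    """Number of incident edges per vertex (handshake: sums to 2|E|)."""
    deg = np.zeros(cx.n_vertices, dtype=np.intp)
    if cx.n_edges:
        np.add.at(deg, cx.edges[:, 0], 1)
        np.add.at(deg, cx.edges[:, 1], 1)
    return deg


def assign_weights(cx: SimplicialComplex) -> WeightAssignment:
    """Degree-based vertex weights and distance-damped edge weights."""
    w_v = 1.0 + degree_sequence(cx).astype(float)
    if cx.n_edges:
        w_e = (w_v[cx.edges[:, 0]] + w_v[cx.edges[:, 1]]) / (1.0 + cx.edge_distances)
    else:
        w_e = np.empty(0, dtype=float)
    return WeightAssignment(vertex_weights=w_v, edge_weights=w_e)
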