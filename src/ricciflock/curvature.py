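"""Forman-Ricci curvature (FRC) of edges and vertices.

For a graph (complex truncated at edges) the weighted FRC of an edge
``a = (u, v)`` with vertex weights w_u, w_v and edge weight w_a is

    R(a) = (w_u + w_v) - w_a * sum over parallel edges a' of
           w_g / sqrt(w_a * w_a'),

where a' ranges over edges sharing exactly one vertex g with a (g is the
shared vertex).  With all weights set to 1 this collapses to the classical
combinatorial form 4 - deg(u) - deg(v).  Strongly negative edges are
information "funnels": both endpoints fan out into many other edges.

The vertex curvature R_i is the sum of R over incident edges, so
sum_i R_i = 2 * sum_e R_e (every edge is counted at both endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complexes import SimplicialComplex, WeightAssignment, degree_sequence

__all__ = [
    "CurvatureReport",
    "edge_frc_combinatorial",
    "edge_frc_weighted",
    "vertex_frc",
    "curvature_report",
]


@dataclass
class CurvatureReport:
    edge_frc: np.ndarray  # (E,)
    vertex_frc: np.ndarray  # (V,); isolated vertices get 0
    mean_vertex_frc: float


def edge_frc_combinatorial(cx: SimplicialComplex) -> np.ndarray:
    """Unit-weight FRC per edge: 4 - deg(u) - deg(v).

    Defined for the graph case; a complex carrying filled triangles must use
    the weighted form with explicit unit weights instead.
    """
    if cx.n_triangles:
        raise ValueError("combinatorial edge FRC is defined for triangle-free complexes")
    deg = degree_sequence(cx)
    if not cx.n_edges:
        return np.empty(0, dtype=float)
    return (4 - deg[cx.edges[:, 0]] - deg[cx.edges[:, 1]]).astype(float)


def edge_frc_weighted(cx: SimplicialComplex, weights: WeightAssignment) -> np.ndarray:
    """Weighted FRC per edge.

    An edge e' parallel to e = (u, v) through shared vertex g contributes
    w_e * w_g / sqrt(w_e * w_e') = w_g * sqrt(w_e / w_e').  Summing over all
    edges at u except e itself (and likewise at v):

        R_e = 2*(w_u + w_v) - sqrt(w_e) * (w_u * s_u + w_v * s_v),

    with s_i = sum over edges e' incident to i of 1/sqrt(w_e'), which is how
    the sum is vectorized here.  No upper (triangle) terms enter: the
    dynamics works with the edge-level reduction where 2-simplices are
    ignored.
    """
    w_v = np.asarray(weights.vertex_weights, dtype=float)
    w_e = np.asarray(weights.edge_weights, dtype=float)
    if w_v.shape[0] != cx.n_vertices or w_e.shape[0] != cx.n_edges:
        raise ValueError("weight arrays do not align with the complex")
    if not cx.n_edges:
        return np.empty(0, dtype=float)
    u, v = cx.edges[:, 0], cx.edges[:, 1]
    inv_sqrt = 1.0 / np.sqrt(w_e)
    s = np.zeros(cx.n_vertices, dtype=float)
    np.add.at(s, u, inv_sqrt)
    np.add.at(s, v, inv_sqrt)
    # subtracting the edge's own 1/sqrt(w_e) term at each endpoint folds the
    # "e' != e" restriction into the incident sums
    lower = w_v[u] + w_v[v]
    parallel = np.sqrt(w_e) * (w_v[u] * (s[u] - inv_sqrt) + w_v[v] * (s[v] - inv_sqrt))
    return lower - parallel


def vertex_frc(cx: SimplicialComplex, edge_curvatures: np.ndarray) -> np.ndarray:
    """Sum of edge curvatures over the edges incident to each vertex."""
    edge_curvatures = np.asarray(edge_curvatures, dtype=float)
    if edge_curvatures.shape[0] != cx.n_edges:
        raise ValueError("edge curvature vector does not align with the edge list")
    out = np.zeros(cx.n_vertices, dtype=float)
    if cx.n_edges:
        np.add.at(out, cx.edges[:, 0], edge_curvatures)
        np.add.at(out, cx.edges[:, 1], edge_curvatures)
    return out


def curvature_report(cx: SimplicialComplex, weights: WeightAssignment) -> CurvatureReport:
    """Weighted edge FRC, vertex FRC and the swarm-mean vertex FRC."""
    r_e = edge_frc_weighted(cx, weights)
    r_i = vertex_frc(cx, r_e)
    return CurvatureReport(edge_frc=r_e, vertex_frc=r_i, mean_vertex_frc=float(r_i.mean()))
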