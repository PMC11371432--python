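"""Small hand-checkable complexes with their known invariants.

Each fixture is a tiny planar point cloud in a large periodic box (so the
minimum-image metric reduces to the plain Euclidean one) together with the
curvatures, Betti numbers and entropy limits worked out by hand.  They
anchor the curvature and Hodge test suites and are emitted by the CLI for
external inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complexes import SimplicialComplex, build_rips
from .geometry import Box

__all__ = ["FixtureComplex", "make_fixture", "FIXTURE_NAMES"]


@dataclass
class FixtureComplex:
    name: str
    points: np.ndarray
    box: Box
    radius: float
    complex: SimplicialComplex
    expected: dict = field(default_factory=dict)


def _fx(name, points, radius, expected, max_dim=1):
    points = np.asarray(points, dtype=float)
    box = Box(L=100.0, d=2)
    cx = build_rips(points, box, radius, max_dim=max_dim)
    return FixtureComplex(
        name=name, points=points, box=box, radius=radius, complex=cx, expected=expected
    )


def make_fixture(name: str) -> FixtureComplex:
    """Deterministic fixture complex with attached hand-computed expectations.

    Known names: isolated_edge, path3, star3, triangle, filled_triangle,
    two_components.
    """
    if name == "isolated_edge":
        # unit edge: degrees (1,1), w_u=w_v=2, weighted R_e = 4, comb. R_e = 2
        return _fx(
            name,
            [[1.0, 1.0], [2.0, 1.0]],
            1.0,
            {
                "betti": (1, 0),
                "chi": 1,
                "edge_frc_combinatorial": [2.0],
                "edge_frc_weighted": [4.0],
                "vertex_frc_weighted": [4.0, 4.0],
                "l0_eigenvalues": [0.0, 2.0],
                "S0_beta1": 0.3653338550872,  # ln(1+e^-2) + 2e^-2/(1+e^-2)
            },
        )
    if name == "path3":
        # a-b-c, unit separations: w=(2,3,2), w_ab=w_bc=2.5, R(ab)=R(bc)=2
        return _fx(
            name,
            [[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]],
            1.0,
            {
                "betti": (1, 0),
                "chi": 1,
                "degrees": [1, 2, 1],
                "vertex_weights": [2.0, 3.0, 2.0],
                "edge_weights": [2.5, 2.5],
                "edge_frc_combinatorial": [1.0, 1.0],
                "edge_frc_weighted": [2.0, 2.0],
                "vertex_frc_weighted": [2.0, 4.0, 2.0],
            },
        )
    if name == "star3":
        # hub at origin with three unit-length leaves
        return _fx(
            name,
            [[5.0, 5.0], [6.0, 5.0], [4.0, 5.0], [5.0, 6.0]],
            1.0,
            {
                "betti": (1, 0),
                "chi": 1,
                "degrees": [3, 1, 1, 1],
                "edge_frc_combinatorial": [0.0, 0.0, 0.0],
            },
        )
    if name == "triangle":
        # unfilled equilateral triangle (side 0.9, safely below the radius):
        # one loop, combinatorial R_e = 0
        pts = [[0.0, 0.0], [0.9, 0.0], [0.45, 0.9 * np.sqrt(3) / 2]]
        return _fx(
            name,
            np.asarray(pts) + 10.0,
            1.0,
            {
                "betti": (1, 1),
                "chi": 0,
                "degrees": [2, 2, 2],
                "edge_frc_combinatorial": [0.0, 0.0, 0.0],
                "l0_eigenvalues": [0.0, 3.0, 3.0],
            },
        )
    if name == "filled_triangle":
        pts = [[0.0, 0.0], [0.9, 0.0], [0.45, 0.9 * np.sqrt(3) / 2]]
        return _fx(
            name,
            np.asarray(pts) + 10.0,
            1.0,
            {"betti": (1, 0, 0), "chi": 1},
            max_dim=2,
        )
    if name == "two_components":
        # two far-apart unit edges: beta_0 = 2, large-beta S0 -> ln 2
        return _fx(
            name,
            [[1.0, 1.0], [2.0, 1.0], [20.0, 20.0], [21.0, 20.0]],
            1.0,
            {"betti": (2, 0), "chi": 2, "S0_large_beta": np.log(2.0)},
        )
    raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURE_NAMES)}")


FIXTURE_NAMES = (
    "isolated_edge",
    "path3",
    "star3",
    "triangle",
    "filled_triangle",
    "two_components",
)
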