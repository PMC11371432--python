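"""Minimum-image metric and isotropic direction sampling in a periodic box.

Agents live on the d-torus [0, L)^d (d = 2 or 3).  All distances are
Euclidean distances between nearest periodic images, computed per axis as
``delta - L * round(delta / L)``, which is exact for a cubic box of edge L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box",
    "min_image_displacement",
    "min_image_distance",
    "pairwise_distances",
    "random_unit_vector",
    "wrap_positions",
]


@dataclass(frozen=True)
class Box:
    """Cubic periodic box of edge length ``L`` in dimension ``d``."""

    L: float
    d: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.L) or self.L <= 0:
            raise ValueError(f"box edge length must be positive and finite, got {self.L}")
        if self.d not in (2, 3):
            raise ValueError(f"supported dimensions are 2 and 3, got {self.d}")

    @property
    def volume(self) -> float:
        return self.L**self.d


def _check_finite(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return a


def min_image_displacement(p: np.ndarray, q: np.ndarray, box: Box) -> np.ndarray:
    """Component-wise displacement q -> p between nearest periodic images."""
    p = _check_finite(p, "p")
    q = _check_finite(q, "q")
    delta = p - q
    return delta - box.L * np.round(delta / box.L)


def min_image_distance(p: np.ndarray, q: np.ndarray, box: Box) -> float:
    """Euclidean distance between the nearest periodic images of p and q.

    Bounded above by (L/2) * sqrt(d) and symmetric in its arguments.
    """
    return float(np.linalg.norm(min_image_displacement(p, q, box)))


def pairwise_distances(positions: np.ndarray, box: Box) -> np.ndarray:
    """Symmetric N x N matrix of minimum-image distances.

    Vectorized equivalent of looping :func:`min_image_distance` over all
    pairs; the diagonal is exactly zero.
    """
    positions = _check_finite(positions, "positions")
    positions = np.atleast_2d(positions)
    if positions.size == 0:
        raise ValueError("positions must contain at least one point")
    delta = positions[:, None, :] - positions[None, :, :]
    delta -= box.L * np.round(delta / box.L)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    np.fill_diagonal(dist, 0.0)
    return dist


def random_unit_vector(d: int, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Isotropic unit vector(s) in d dimensions.

    2D draws a uniform angle; 3D normalizes standard-normal triples.  Both
    are exactly isotropic.  With ``size=None`` returns shape (d,), otherwise
    (size, d); the ``size=n`` batch consumes the generator identically to n
    successive single draws.
    """
    if d == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=size)
        return np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    if d == 3:
        shape = (3,) if size is None else (size, 3)
        v = rng.standard_normal(shape)
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        # Degenerate all-zero normal triples have probability zero but would
        # divide by zero; redraw defensively.
        while np.any(norm == 0.0):  # pragma: no cover
            bad = (norm == 0.0).ravel()
            v[bad] = rng.standard_normal((int(bad.sum()), 3))
            norm = np.linalg.norm(v, axis=-1, keepdims=True)
        return v / norm
    raise ValueError(f"supported dimensions are 2 and 3, got {d}")


def wrap_positions(positions: np.ndarray, box: Box) -> np.ndarray:
    """Map every coordinate to the canonical representative in [0, L)."""
    positions = _check_finite(positions, "positions")
    return np.mod(positions, box.L)
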