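"""Summary statistics of the swarm: order parameter, g(r), mean curvature.

The polar order parameter is the norm of the mean heading unit vector,

    phi_v = (1/N) || sum_i v_i / ||v_i|| ||,

1 for perfect alignment and about c/sqrt(N) for isotropic headings
(Rayleigh null; c = sqrt(pi)/2 in 2D).  The radial distribution function
g(r) is the shell-normalized pair density under minimum-image distances:
1 everywhere for an ideal gas, peaks signal clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Box, pairwise_distances

__all__ = [
    "ObservableSeries",
    "RadialDistribution",
    "order_parameter",
    "radial_distribution",
    "mean_vertex_frc",
    "aggregate_samples",
]


@dataclass
class ObservableSeries:
    """Time-indexed observables of one run (or a cross-sample mean).

    Entropy and Betti series carry NaN at steps where topology was not
    evaluated (they are recorded on their own, sparser cadence because the
    eigenproblems dominate the cost).  ``se_*`` fields are populated only on
    aggregated series.
    """

    steps: np.ndarray
    phi_v: np.ndarray
    mean_R: np.ndarray
    S0: np.ndarray
    S1: np.ndarray
    betti0: np.ndarray
    betti1: np.ndarray
    se_phi_v: np.ndarray | None = None
    se_mean_R: np.ndarray | None = None
    n_samples: int = 1

    def __post_init__(self) -> None:
        lengths = {
            len(self.steps), len(self.phi_v), len(self.mean_R),
            len(self.S0), len(self.S1), len(self.betti0), len(self.betti1),
        }
        if len(lengths) != 1:
            raise ValueError("observable series have inconsistent lengths")

    def terminal_mean(self, field_name: str = "phi_v", window: float = 0.2) -> float:
        """Mean of a series over the final ``window`` fraction of records."""
        values = getattr(self, field_name)
        tail = max(1, int(np.ceil(window * len(values))))
        return float(np.nanmean(values[-tail:]))

    def to_frame(self):
        import pandas as pd

        data = {
            "step": self.steps, "phi_v": self.phi_v, "mean_R": self.mean_R,
            "S0": self.S0, "S1": self.S1, "betti0": self.betti0, "betti1": self.betti1,
        }
        if self.se_phi_v is not None:
            data["se_phi_v"] = self.se_phi_v
            data["se_mean_R"] = self.se_mean_R
        return pd.DataFrame(data)


@dataclass
class RadialDistribution:
    bin_edges: np.ndarray  # (B+1,)
    g: np.ndarray  # (B,)
    density: float
    n_reference: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def order_parameter(velocities: np.ndarray) -> float:
    """Norm of the mean heading unit vector, in [0, 1]."""
    velocities = np.asarray(velocities, dtype=float)
    speeds = np.linalg.norm(velocities, axis=1)
    if np.any(speeds == 0):
        raise ValueError("zero-speed agent: heading undefined")
    headings = velocities / speeds[:, None]
    return float(np.linalg.norm(headings.mean(axis=0)))


def _shell_volumes(edges: np.ndarray, d: int) -> np.ndarray:
    """Exact annulus (2D) or spherical-shell (3D) volumes from bin edges."""
    if d == 2:
        return np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)


def radial_distribution(
    positions: np.ndarray,
    box: Box,
    dr: float = 0.1,
    dist: np.ndarray | None = None,
) -> RadialDistribution:
    """g(r) on bins of width ``dr`` covering (0, L/2].

    Ordered pair counts per shell are averaged over reference agents and
    divided by rho * shell volume, evaluated exactly from the bin edges
    (midpoint shell volumes would bias small-r bins by O(dr)).  r stops at
    L/2, the validity bound of the minimum-image metric.
    """
    if dr <= 0:
        raise ValueError(f"bin width must be positive, got {dr}")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    if dist is None:
        dist = pairwise_distances(positions, box)
    r_max = box.L / 2.0
    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    iu, ju = np.triu_indices(n, k=1)
    counts, _ = np.histogram(dist[iu, ju], bins=edges)
    rho = n / box.volume
    shells = _shell_volumes(edges, box.d)
    # 2*counts: ordered pairs; /n: average over reference agents
    g = 2.0 * counts / (n * rho * shells)
    return RadialDistribution(bin_edges=edges, g=g, density=rho, n_reference=n)


def accumulate_radial(dists: list[np.ndarray], box: Box, n: int, dr: float = 0.1) -> RadialDistribution:
    """g(r) pooled over several snapshots' distance matrices (equal N)."""
    if not dists:
        raise ValueError("no snapshots to accumulate")
    r_max = box.L / 2.0
    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    iu, ju = np.triu_indices(n, k=1)
    counts = np.zeros(len(edges) - 1)
    for dmat in dists:
        c, _ = np.histogram(dmat[iu, ju], bins=edges)
        counts += c
    rho = n / box.volume
    g = 2.0 * counts / (len(dists) * n * rho * _shell_volumes(edges, box.d))
    return RadialDistribution(bin_edges=edges, g=g, density=rho, n_reference=n)


def mean_vertex_frc(reports) -> float:
    """Grand mean of vertex curvature over agents and recorded steps."""
    all_r = [np.asarray(rep.vertex_frc, dtype=float) for rep in reports]
    if not all_r:
        raise ValueError("no curvature reports supplied")
    return float(np.concatenate(all_r).mean())


def aggregate_samples(samples: list[ObservableSeries]) -> ObservableSeries:
    """Pointwise mean and standard error across independent runs."""
    if not samples:
        raise ValueError("no samples to aggregate")
    length = len(samples[0].steps)
    if any(len(s.steps) != length for s in samples):
        raise ValueError("samples have mismatched lengths")
    m = len(samples)

    def stack(name):
        return np.stack([getattr(s, name) for s in samples])

    def se(a):
        return a.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros(a.shape[1])

    phi = stack("phi_v")
    mr = stack("mean_R")
    import warnings

    with warnings.catch_warnings():
        # topology series are all-NaN when entropy recording is disabled
        warnings.simplefilter("ignore", RuntimeWarning)
        return ObservableSeries(
            steps=samples[0].steps.copy(),
            phi_v=phi.mean(axis=0),
            mean_R=mr.mean(axis=0),
            S0=np.nanmean(stack("S0"), axis=0),
            S1=np.nanmean(stack("S1"), axis=0),
            betti0=np.nanmean(stack("betti0"), axis=0),
            betti1=np.nanmean(stack("betti1"), axis=0),
            se_phi_v=se(phi),
            se_mean_R=se(mr),
            n_samples=m,
        )
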