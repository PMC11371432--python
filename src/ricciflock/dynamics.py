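"""Curvature-driven update rule with annular neighbourhoods, plus the
metric Vicsek baseline, and the synchronous time-stepping loop.

Each step rebuilds the Vietoris-Rips complex of the whole swarm at
filtration radius ``rmax``, assigns degree/distance weights, computes the
weighted Forman-Ricci curvature of every edge and vertex, and then every
agent simultaneously reorients:

* ``curvature`` mode -- among candidates at distance in [rmin, rmax] the
  agent picks the k with the *lowest* vertex curvature (the most "funnel"-
  like information hubs) and takes the vertex-weight-weighted mean of their
  headings; with rmin > 0 the closest agents are excluded, which is the
  non-local variant.
* ``vicsek`` mode -- the classical rule: unweighted mean heading over the
  metric neighbourhood including the agent itself.

In both modes a noise kick v0 * eta * r_hat (r_hat an isotropic unit
vector) perturbs the new heading, after which the speed is renormalized to
exactly v0: agents move at constant speed, so noise acts purely on heading.
Positions then advance by one unit time step of the new velocity and wrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .complexes import assign_weights, complex_from_distance_matrix
from .curvature import CurvatureReport, curvature_report
from .geometry import Box, pairwise_distances, random_unit_vector, wrap_positions
from .hodge import edge_spectrum_from_graph, hodge_laplacian, spectral_entropy
from .observables import (
    ObservableSeries,
    RadialDistribution,
    accumulate_radial,
    aggregate_samples,
    order_parameter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "AgentState",
    "RunResult",
    "initialize_state",
    "annulus_candidates",
    "select_topological_neighbours",
    "update_velocity",
    "step",
    "run",
]


@dataclass(frozen=True)
class SimConfig:
    """All parameters of one simulation.

    The box edge follows from density: L = (N / rho)^(1/d).  Defaults are
    the 2D reference conditions: unit density, speed 0.5, unit-width
    interaction annulus, one effective neighbour.
    """

    N: int = 100
    d: int = 2
    rho: float = 1.0
    v0: float = 0.5
    eta: float = 0.0
    rmin: float = 0.0
    rmax: float = 1.0
    k: int = 1
    steps: int = 5000
    samples: int = 10
    seed: int = 0
    mode: str = "curvature"
    hodge_beta: float = 1.0
    max_dim: int = 1
    record_every: int = 10
    topology_every: int = 0  # 0 disables entropy/Betti recording
    dr: float = 0.1  # g(r) bin width
    gr_window: float = 0.2  # trailing fraction of steps feeding g(r)
    record_gr: bool = False
    exclude_short_edges: bool = False

    def __post_init__(self) -> None:
        problems = []
        if self.N < 1:
            problems.append(f"N must be >= 1, got {self.N}")
        if self.d not in (2, 3):
            problems.append(f"d must be 2 or 3, got {self.d}")
        if self.rho <= 0:
            problems.append(f"rho must be positive, got {self.rho}")
        if self.v0 <= 0:
            problems.append(f"v0 must be positive, got {self.v0}")
        if self.eta < 0:
            problems.append(f"eta must be nonnegative, got {self.eta}")
        if not 0 <= self.rmin < self.rmax:
            problems.append(f"need 0 <= rmin < rmax, got rmin={self.rmin} rmax={self.rmax}")
        if self.k < 1:
            problems.append(f"k must be >= 1, got {self.k}")
        if self.steps < 0 or self.samples < 1:
            problems.append("steps must be >= 0 and samples >= 1")
        if self.mode not in ("curvature", "vicsek"):
            problems.append(f"mode must be 'curvature' or 'vicsek', got {self.mode!r}")
        if self.hodge_beta <= 0:
            problems.append(f"hodge_beta must be positive, got {self.hodge_beta}")
        if self.record_every < 1:
            problems.append("record_every must be >= 1")
        if self.topology_every < 0 or (
            self.topology_every and self.topology_every % self.record_every
        ):
            problems.append("topology_every must be 0 or a multiple of record_every")
        if self.dr <= 0 or not 0 < self.gr_window <= 1:
            problems.append("dr must be positive and gr_window in (0, 1]")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @property
    def L(self) -> float:
        return (self.N / self.rho) ** (1.0 / self.d)

    @property
    def box(self) -> Box:
        return Box(L=self.L, d=self.d)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in fields(cls)}


@dataclass
class AgentState:
    """Positions in [0, L)^d and velocities of row norm v0 at one step."""

    positions: np.ndarray
    velocities: np.ndarray
    time: int = 0


@dataclass
class RunResult:
    samples: list[ObservableSeries]
    mean: ObservableSeries
    gr: RadialDistribution | None = None
    config: SimConfig | None = None


def initialize_state(cfg: SimConfig, rng: np.random.Generator) -> AgentState:
    """Uniform random positions in the box, isotropic headings at speed v0."""
    positions = rng.uniform(0.0, cfg.L, size=(cfg.N, cfg.d))
    velocities = cfg.v0 * random_unit_vector(cfg.d, rng, size=cfg.N)
    return AgentState(positions=positions, velocities=velocities, time=0)


def annulus_candidates(agent: int, dist: np.ndarray, rmin: float, rmax: float) -> np.ndarray:
    """Indices j != agent with rmin <= d(agent, j) <= rmax (closed interval)."""
    row = dist[agent]
    mask = (row >= rmin) & (row <= rmax)
    mask[agent] = False
    return np.nonzero(mask)[0]


def select_topological_neighbours(
    candidates: np.ndarray, vertex_curvature: np.ndarray, k: int
) -> np.ndarray:
    """The min(k, |candidates|) candidates of smallest vertex curvature.

    Ties break toward the lower agent index; always follows the most
    negatively curved available agents even when all candidate curvatures
    are positive.
    """
    candidates = np.asarray(candidates, dtype=np.intp)
    if candidates.size == 0:
        return candidates
    candidates = np.sort(candidates)
    order = np.argsort(vertex_curvature[candidates], kind="stable")
    return candidates[order[: min(k, candidates.size)]]


def _renormalize(direction: np.ndarray, own_velocity: np.ndarray, v0: float) -> np.ndarray:
    norm = np.linalg.norm(direction)
    if norm == 0.0:
        logger.debug("zero-norm heading sum; falling back to own heading")
        return own_velocity.copy()
    return v0 * direction / norm


def update_velocity(
    agent: int,
    state: AgentState,
    selected: np.ndarray,
    vertex_weights: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """New velocity of one agent from the time-t state (reference path).

    Weighted mean of the selected neighbours' velocities (vertex weights of
    the neighbours), renormalized to v0, plus the noise kick, renormalized
    again.  An empty selection keeps the agent's own heading.  The
    time-stepping loop uses a vectorized equivalent of this function.
    """
    selected = np.asarray(selected, dtype=np.intp)
    own = state.velocities[agent]
    if selected.size:
        vsum = (vertex_weights[selected, None] * state.velocities[selected]).sum(axis=0)
    else:
        vsum = own.copy()
    v_new = _renormalize(vsum, own, cfg.v0)
    noise = random_unit_vector(cfg.d, rng)
    v_new = v_new + cfg.v0 * cfg.eta * noise
    return _renormalize(v_new, own, cfg.v0)


@dataclass
class StepDiagnostics:
    """Per-step intermediates reused by observable recording."""

    dist: np.ndarray
    curvature: CurvatureReport
    n_edges: int
    complex_: object = None


def _analyze(state: AgentState, cfg: SimConfig) -> StepDiagnostics:
    dist = pairwise_distances(state.positions, cfg.box)
    cx = complex_from_distance_matrix(
        dist,
        cfg.rmax,
        max_dim=cfg.max_dim,
        exclude_below=cfg.rmin if cfg.exclude_short_edges else None,
    )
    report = curvature_report(cx, assign_weights(cx))
    return StepDiagnostics(dist=dist, curvature=report, n_edges=cx.n_edges, complex_=cx)


def _new_velocities(
    state: AgentState, cfg: SimConfig, diag: StepDiagnostics, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized synchronous velocity update for all agents."""
    n, v0 = cfg.N, cfg.v0
    dist = diag.dist
    mask = (dist >= cfg.rmin) & (dist <= cfg.rmax)
    np.fill_diagonal(mask, False)

    if cfg.mode == "vicsek":
        np.fill_diagonal(mask, True)  # classical rule averages the agent itself in
        vsum = mask.astype(float) @ state.velocities
    else:
        r_i = diag.curvature.vertex_frc
        key = np.where(mask, r_i[None, :], np.inf)
        order = np.argsort(key, axis=1, kind="stable")  # stable: ties -> lower index
        take = np.minimum(mask.sum(axis=1), cfg.k)
        sel = order[:, : cfg.k]
        valid = np.arange(cfg.k)[None, :] < take[:, None]
        w_v = _vertex_weights_from(diag)
        w_sel = np.where(valid, w_v[sel], 0.0)
        vsum = np.einsum("ik,ikd->id", w_sel, state.velocities[sel])

    norms = np.linalg.norm(vsum, axis=1)
    fallback = norms == 0.0
    if np.any(fallback):
        vsum[fallback] = state.velocities[fallback]
        norms[fallback] = v0
    v_new = v0 * vsum / norms[:, None]

    noise = random_unit_vector(cfg.d, rng, size=n)
    v_new = v_new + v0 * cfg.eta * noise
    norms = np.linalg.norm(v_new, axis=1)
    dead = norms == 0.0
    if np.any(dead):  # exact cancellation by the noise kick: keep old heading
        logger.debug("noise cancelled heading for %d agents", int(dead.sum()))
        v_new[dead] = state.velocities[dead]
        norms[dead] = v0
    return v0 * v_new / norms[:, None]


def _vertex_weights_from(diag: StepDiagnostics) -> np.ndarray:
    cx = diag.complex_
    deg = np.zeros(cx.n_vertices)
    if cx.n_edges:
        np.add.at(deg, cx.edges[:, 0], 1.0)
        np.add.at(deg, cx.edges[:, 1], 1.0)
    return 1.0 + deg


def step(
    state: AgentState,
    cfg: SimConfig,
    rng: np.random.Generator,
    diag: StepDiagnostics | None = None,
) -> AgentState:
    """One synchronous update: rebuild complex, reorient all agents from
    time-t quantities, advance positions by the new velocities, wrap."""
    if diag is None:
        diag = _analyze(state, cfg)
    v_new = _new_velocities(state, cfg, diag, rng)
    positions = wrap_positions(state.positions + v_new, cfg.box)
    return AgentState(positions=positions, velocities=v_new, time=state.time + 1)


def _record_topology(diag: StepDiagnostics, cfg: SimConfig) -> tuple[float, float, int, int]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    cx = diag.complex_
    if cx.n_edges:
        adj = csr_matrix(
            (np.ones(cx.n_edges), (cx.edges[:, 0], cx.edges[:, 1])),
            shape=(cx.n_vertices, cx.n_vertices),
        )
        b0 = int(connected_components(adj, directed=False, return_labels=False))
    else:
        b0 = cx.n_vertices
    b1 = cx.n_edges - cx.n_vertices + b0  # triangle-free complex
    lam0 = np.linalg.eigvalsh(hodge_laplacian(cx, 0))
    s0 = spectral_entropy(lam0, cfg.hodge_beta, order=0)
    if cx.n_edges:
        s1 = edge_spectrum_from_graph(lam0, cx.n_edges, b0, b1, beta=cfg.hodge_beta).entropy
    else:
        s1 = 0.0
    return s0, s1, b0, b1


def _run_single(cfg: SimConfig, seed: int) -> tuple[ObservableSeries, list[np.ndarray]]:
    rng = np.random.default_rng(seed)
    state = initialize_state(cfg, rng)
    rec_steps, phi, mean_r, s0s, s1s, b0s, b1s = [], [], [], [], [], [], []
    gr_snapshots: list[np.ndarray] = []
    gr_start = cfg.steps - cfg.gr_window * cfg.steps

    for t in range(cfg.steps + 1):
        want_record = t % cfg.record_every == 0 or t == cfg.steps
        diag = _analyze(state, cfg) if (want_record or t < cfg.steps) else None
        if want_record:
            rec_steps.append(t)
            phi.append(order_parameter(state.velocities))
            mean_r.append(diag.curvature.mean_vertex_frc)
            if cfg.topology_every and t % cfg.topology_every == 0:
                s0, s1, b0, b1 = _record_topology(diag, cfg)
            else:
                s0 = s1 = b0 = b1 = np.nan
            s0s.append(s0)
            s1s.append(s1)
            b0s.append(b0)
            b1s.append(b1)
            if cfg.record_gr and t >= gr_start:
                gr_snapshots.append(diag.dist)
        if t < cfg.steps:
            state = step(state, cfg, rng, diag=diag)

    series = ObservableSeries(
        steps=np.asarray(rec_steps),
        phi_v=np.asarray(phi),
        mean_R=np.asarray(mean_r),
        S0=np.asarray(s0s, dtype=float),
        S1=np.asarray(s1s, dtype=float),
        betti0=np.asarray(b0s, dtype=float),
        betti1=np.asarray(b1s, dtype=float),
    )
    return series, gr_snapshots


def iterate_states(cfg: SimConfig, seed: int):
    """Yield the initial state and every subsequent state of one run."""
    rng = np.random.default_rng(seed)
    state = initialize_state(cfg, rng)
    yield state
    for _ in range(cfg.steps):
        state = step(state, cfg, rng)
        yield state


def run(cfg: SimConfig) -> RunResult:
    """Ensemble of independent runs; per-sample series plus their mean.

    Sample s uses seed ``cfg.seed + s`` so ensembles are reproducible and
    non-overlapping for small seed offsets.
    """
    all_series: list[ObservableSeries] = []
    gr_all: list[np.ndarray] = []
    for s in range(cfg.samples):
        series, snaps = _run_single(cfg, cfg.seed + s)
        all_series.append(series)
        gr_all.extend(snaps)
        logger.info("sample %d/%d done (terminal phi=%.4f)", s + 1, cfg.samples,
                    series.phi_v[-1])
    gr = accumulate_radial(gr_all, cfg.box, cfg.N, dr=cfg.dr) if gr_all else None
    return RunResult(samples=all_series, mean=aggregate_samples(all_series), gr=gr,
                     config=cfg)
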