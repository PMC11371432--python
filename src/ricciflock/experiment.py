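"""Config parsing, experiment runners, parameter sweeps and cloud analysis.

An *experiment* is an ensemble of independent simulations of one
configuration; a *sweep* repeats an experiment over a grid of one parameter
(typically the noise strength eta, the neighbour count k, or the annulus
inner radius rmin) and tabulates terminal-window means, which is how the
order-disorder transition curves are produced.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .complexes import assign_weights, build_rips
from .curvature import curvature_report
from .dynamics import RunResult, SimConfig, iterate_states, run
from .geometry import Box
from .hodge import betti_numbers, hodge_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSpec",
    "load_config",
    "run_experiment",
    "run_sweep",
    "analyze_cloud",
    "dump_trajectory",
    "PRESETS",
]

# Reference study conditions: unit density, v0 = 0.5, unit-width annulus,
# ensembles of 10.  The desk presets use 5000 steps (order saturates early);
# the *_full presets carry the long-run protocol (1e5 steps, N=1000 in 3D).
PRESETS: dict[str, dict] = {
    "2d-local": dict(N=100, d=2, rmin=0.0, rmax=1.0),
    "2d-nonlocal": dict(N=100, d=2, rmin=1.0, rmax=2.0),
    "3d-local": dict(N=200, d=3, rmin=0.0, rmax=1.0),
    "3d-nonlocal": dict(N=200, d=3, rmin=1.0, rmax=2.0),
    "3d-local-full": dict(N=1000, d=3, rmin=0.0, rmax=1.0, steps=100_000),
    "3d-nonlocal-full": dict(N=1000, d=3, rmin=1.0, rmax=2.0, steps=100_000),
    "2d-local-full": dict(N=100, d=2, rmin=0.0, rmax=1.0, steps=100_000),
}


@dataclass
class SweepSpec:
    """One-parameter grid over a base configuration."""

    parameter: str
    values: list
    base: SimConfig

    def __post_init__(self) -> None:
        if self.parameter not in ("eta", "k", "rmin", "d"):
            raise ValueError(f"sweepable parameters are eta, k, rmin, d; got {self.parameter!r}")
        if not self.values:
            raise ValueError("sweep value list is empty")
        for v in self.values:
            if not np.isfinite(v):
                raise ValueError(f"non-finite sweep value {v!r}")

    def configs(self) -> list[SimConfig]:
        out = []
        for v in self.values:
            kw = {self.parameter: v}
            if self.parameter == "rmin":
                # preserve the unit-width annulus when sliding rmin
                kw["rmax"] = v + (self.base.rmax - self.base.rmin)
            out.append(self.base.replace(**kw))
        return out


def load_config(path: str | Path, **overrides) -> SimConfig:
    """SimConfig from a YAML or JSON mapping; unknown keys are rejected.

    ``overrides`` (e.g. CLI flags) take precedence over file values.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - SimConfig.field_names()
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return SimConfig(**raw)


def run_experiment(cfg: SimConfig, outdir: str | Path) -> RunResult:
    """Run an ensemble and write per-sample CSVs, the mean CSV, the g(r)
    table and a JSON echo of the configuration with seed provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    result = run(cfg)
    elapsed = time.perf_counter() - t0

    for s, series in enumerate(result.samples):
        series.to_frame().to_csv(outdir / f"observables_sample{s:02d}.csv", index=False)
    result.mean.to_frame().to_csv(outdir / "observables_mean.csv", index=False)
    if result.gr is not None:
        pd.DataFrame(
            {
                "r_lo": result.gr.bin_edges[:-1],
                "r_hi": result.gr.bin_edges[1:],
                "g": result.gr.g,
            }
        ).to_csv(outdir / "gr.csv", index=False)
    echo = {f: getattr(cfg, f) for f in sorted(SimConfig.field_names())}
    echo["sample_seeds"] = [cfg.seed + s for s in range(cfg.samples)]
    echo["wall_time_s"] = round(elapsed, 3)
    (outdir / "config.json").write_text(json.dumps(echo, indent=2) + "\n")
    logger.info("experiment written to %s (%.1fs)", outdir, elapsed)
    return result


def dump_trajectory(cfg: SimConfig, path: str | Path, sample: int = 0) -> None:
    """Write one sample's trajectory: step, agent, x, y[, z], vx, vy[, vz].

    Rows are emitted at the observable cadence (``record_every``).
    """
    coords = ["x", "y", "z"][: cfg.d]
    rows = []
    for state in iterate_states(cfg, cfg.seed + sample):
        if state.time % cfg.record_every and state.time != cfg.steps:
            continue
        for i in range(cfg.N):
            rows.append(
                [state.time, i, *state.positions[i], *state.velocities[i]]
            )
    df = pd.DataFrame(rows, columns=["step", "agent", *coords, *[f"v{c}" for c in coords]])
    df.to_csv(path, index=False)


def run_sweep(spec: SweepSpec, outdir: str | Path, window: float = 0.2) -> pd.DataFrame:
    """One experiment per sweep value plus a terminal-window summary table.

    The summary holds, per value, the cross-sample mean (and standard error)
    of the order parameter and the mean vertex curvature over the final
    ``window`` fraction of recorded steps -- the quantities plotted against
    noise in transition diagrams.  Failures of individual values are logged
    and skipped so a long sweep survives a bad point.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for value, cfg in zip(spec.values, spec.configs()):
        sub = outdir / f"{spec.parameter}={value}"
        try:
            result = run_experiment(cfg, sub)
        except Exception:
            logger.exception("sweep point %s=%s failed; continuing", spec.parameter, value)
            continue
        terminal_phi = [s.terminal_mean("phi_v", window) for s in result.samples]
        terminal_r = [s.terminal_mean("mean_R", window) for s in result.samples]
        rows.append(
            {
                spec.parameter: value,
                "phi_v": float(np.mean(terminal_phi)),
                "se_phi_v": float(np.std(terminal_phi, ddof=1) / np.sqrt(len(terminal_phi)))
                if len(terminal_phi) > 1
                else 0.0,
                "mean_R": float(np.mean(terminal_r)),
                "se_mean_R": float(np.std(terminal_r, ddof=1) / np.sqrt(len(terminal_r)))
                if len(terminal_r) > 1
                else 0.0,
                "samples": cfg.samples,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "sweep_summary.csv", index=False)
    return summary


def analyze_cloud(
    points: np.ndarray,
    r: float,
    box: Box | None = None,
    beta: float = 1.0,
    max_dim: int = 1,
) -> dict:
    """Standalone topological analysis of a point cloud.

    Builds the Rips complex at radius ``r`` (periodic if a box is given,
    otherwise in a box large enough that wrapping never triggers), and
    returns curvatures, Betti numbers, Euler characteristic and spectral
    entropies as plain Python types suitable for JSON output.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = points.shape
    if box is None:
        span = float(points.max() - min(points.min(), 0.0)) + 4.0 * r
        box = Box(L=span, d=d)
    cx = build_rips(points, box, r, max_dim=max_dim)
    weights = assign_weights(cx)
    report = curvature_report(cx, weights)
    topo = betti_numbers(cx)
    s0 = hodge_spectrum(cx, 0, beta=beta).entropy
    s1 = hodge_spectrum(cx, 1, beta=beta).entropy if cx.n_edges else 0.0
    return {
        "n_points": int(n),
        "n_edges": int(cx.n_edges),
        "n_triangles": int(cx.n_triangles),
        "radius": float(r),
        "betti": [int(b) for b in topo.betti],
        "euler_characteristic": int(topo.euler_characteristic),
        "edge_frc": [float(x) for x in report.edge_frc],
        "vertex_frc": [float(x) for x in report.vertex_frc],
        "mean_vertex_frc": float(report.mean_vertex_frc),
        "S0": float(s0),
        "S1": float(s1),
        "hodge_beta": float(beta),
    }


def load_cloud_csv(path: str | Path, columns: list[str] | None = None) -> np.ndarray:
    """Point cloud from CSV: one row per point, coordinate columns x,y[,z].

    Headerless numeric files are accepted; with a header, ``columns``
    selects the coordinate columns (default x, y and z when present).
    """
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    has_header = any(c.isalpha() for c in first.split(",")[0])
    if has_header:
        df = pd.read_csv(path)
        cols = columns or [c for c in ("x", "y", "z") if c in df.columns]
        if not cols:
            raise ValueError(f"{path}: no coordinate columns found (expected x,y[,z])")
        return df[cols].to_numpy(dtype=float)
    return pd.read_csv(path, header=None).to_numpy(dtype=float)
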