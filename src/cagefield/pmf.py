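"""Jarzynski / adaptive-steering free-energy estimation from work traces.

Jarzynski's equality, ⟨exp(−βW)⟩ = exp(−βΔG), turns an ensemble of
nonequilibrium work values into an equilibrium free-energy difference.
The exponential average is evaluated in a shifted (log-sum-exp) form so
large βW never under/overflows.

Staged pulling (the adaptive steered-MD layout: here 10 stages across a
3→23 Å coordinate by default) is stitched stagewise: each stage's work
increments are re-zeroed at the stage boundary — the work level of the
"adaptive" restart from the configuration nearest the stage average —
Jarzynski-averaged independently, and the per-stage ΔG accumulated.  A
full-trace (non-adaptive) estimator is provided for comparison.
Uncertainty comes from a percentile bootstrap over trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import R_GAS_KCAL
from .errors import FormatError, ParameterError

__all__ = [
    "WorkTraces", "PmfCurve",
    "jarzynski_dg", "bootstrap_ci", "asmd_stitch", "full_trace_pmf",
    "read_work_csv", "write_work_csv",
]


@dataclass(frozen=True)
class WorkTraces:
    """Accumulated-work curves over staged reaction-coordinate windows.

    ``stages`` are the n+1 strictly increasing stage breakpoints (Å) for n
    stages; ``coordinates`` the sample points (≥ breakpoints, here equal
    to them); ``traces`` the [trajectory × sample point] cumulative work
    in kcal/mol, zero at the first point.
    """

    stages: np.ndarray        # breakpoints, Å
    coordinates: np.ndarray   # sample points, Å
    traces: np.ndarray        # (n_traj, n_points), kcal/mol
    temperature: float        # K

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", np.asarray(self.stages, dtype=float))
        object.__setattr__(self, "coordinates", np.asarray(self.coordinates, dtype=float))
        object.__setattr__(self, "traces", np.atleast_2d(np.asarray(self.traces, dtype=float)))
        if np.any(np.diff(self.stages) <= 0):
            raise ParameterError("stage breakpoints must be strictly increasing")
        if self.traces.shape[1] != len(self.coordinates):
            raise ParameterError("traces second dimension must match coordinates")

    @property
    def n_traj(self) -> int:
        return self.traces.shape[0]

    @property
    def n_stages(self) -> int:
        return len(self.stages) - 1


@dataclass(frozen=True)
class PmfCurve:
    """Free-energy profile relative to the first grid point, with bootstrap CI."""

    coordinate: np.ndarray   # Å
    dg: np.ndarray           # kcal/mol, dg[0] = 0
    ci_low: np.ndarray
    ci_high: np.ndarray
    stage_dg: np.ndarray     # per-stage increments, kcal/mol
    stage_se: np.ndarray     # bootstrap SE of the cumulative dg at stage ends
    n_traj: int
    temperature: float


def jarzynski_dg(works: np.ndarray, temperature: float) -> float:
    """Jarzynski free-energy estimate ΔG = −β⁻¹ ln ⟨exp(−βW)⟩, kcal/mol.

    Evaluated via log-sum-exp so arbitrarily large |βW| is safe.  Raises
    on empty input or non-finite work values (naming the first offender).
    """
    works = np.asarray(works, dtype=float)
    if works.size == 0:
        raise ParameterError("empty work vector")
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    bad = np.flatnonzero(~np.isfinite(works))
    if bad.size:
        raise ParameterError(f"non-finite work value at index {bad[0]}")
    beta = 1.0 / (R_GAS_KCAL * temperature)
    return float(-(logsumexp(-beta * works) - np.log(works.size)) / beta)


def bootstrap_ci(
    works: np.ndarray,
    temperature: float,
    n_bootstrap: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for :func:`jarzynski_dg`.

    Deterministic for a fixed seed; requires ``n_bootstrap`` ≥ 100 so the
    percentile tails are populated.
    """
    works = np.asarray(works, dtype=float)
    if not 0.0 < level < 1.0:
        raise ParameterError("level must be in (0, 1)")
    if n_bootstrap < 100:
        raise ParameterError("n_bootstrap must be at least 100")
    rng = np.random.default_rng(seed)
    n = works.size
    estimates = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        estimates[b] = jarzynski_dg(works[rng.integers(0, n, n)], temperature)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(estimates, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def _stage_columns(traces: WorkTraces) -> list[tuple[int, int]]:
    """(start, end) column index per stage, matching coordinates to breakpoints."""
    cols = []
    coord = traces.coordinates
    for s in range(traces.n_stages):
        start = int(np.argmin(np.abs(coord - traces.stages[s])))
        end = int(np.argmin(np.abs(coord - traces.stages[s + 1])))
        if end <= start:
            raise ParameterError(f"stage {s} has no coordinate span")
        cols.append((start, end))
    return cols


def _stitch(traces_arr: np.ndarray, cols: list[tuple[int, int]],
            temperature: float) -> tuple[np.ndarray, np.ndarray]:
    """Stagewise-re-zeroed Jarzynski stitch → (per-stage ΔG, cumulative curve)."""
    stage_dg = np.empty(len(cols))
    curve = [0.0]
    anchor = 0.0
    for s, (c0, c1) in enumerate(cols):
        inc = traces_arr[:, c0 + 1 : c1 + 1] - traces_arr[:, c0:c0 + 1]
        point_dg = np.array([jarzynski_dg(inc[:, j], temperature)
                             for j in range(inc.shape[1])])
        curve.extend(anchor + point_dg)
        stage_dg[s] = point_dg[-1]
        anchor += point_dg[-1]
    return stage_dg, np.array(curve)


def asmd_stitch(
    traces: WorkTraces,
    n_bootstrap: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> PmfCurve:
    """Stagewise Jarzynski PMF with percentile-bootstrap confidence bands.

    Per stage, work increments are re-zeroed at the stage boundary and
    Jarzynski-averaged; the cumulative sum (anchored at 0) is the PMF.
    Bootstrap resamples whole trajectories, so bands reflect between-
    trajectory variability including the stitching.
    """
    if traces.n_traj < 2:
        raise ParameterError("need at least 2 trajectories per stage")
    cols = _stage_columns(traces)
    stage_dg, curve = _stitch(traces.traces, cols, traces.temperature)

    rng = np.random.default_rng(seed)
    n = traces.n_traj
    boot = np.empty((n_bootstrap, len(curve)))
    for b in range(n_bootstrap):
        sample = traces.traces[rng.integers(0, n, n)]
        boot[b] = _stitch(sample, cols, traces.temperature)[1]
    alpha = 100.0 * (1.0 - level) / 2.0
    ci_low = np.percentile(boot, alpha, axis=0)
    ci_high = np.percentile(boot, 100.0 - alpha, axis=0)
    # bands are for the curve; make them contain the point estimate
    ci_low = np.minimum(ci_low, curve)
    ci_high = np.maximum(ci_high, curve)
    stage_ends = np.cumsum([0] + [c1 - c0 for c0, c1 in cols])
    stage_se = boot[:, stage_ends].std(axis=0, ddof=1)
    return PmfCurve(
        coordinate=traces.coordinates.copy(),
        dg=curve,
        ci_low=ci_low,
        ci_high=ci_high,
        stage_dg=stage_dg,
        stage_se=stage_se,
        n_traj=n,
        temperature=traces.temperature,
    )


def full_trace_pmf(traces: WorkTraces) -> np.ndarray:
    """Non-adaptive estimate: Jarzynski on cumulative work at each point."""
    w = traces.traces
    return np.array([jarzynski_dg(w[:, j] - w[:, 0], traces.temperature)
                     for j in range(w.shape[1])])


# ---------------------------------------------------------------------------
# Long-form CSV I/O: traj_id, stage, coordinate, cumulative_work
# ---------------------------------------------------------------------------

def write_work_csv(traces: WorkTraces, path: str | Path) -> None:
    cols = _stage_columns(traces)
    stage_of_point = np.zeros(len(traces.coordinates), dtype=int)
    for s, (c0, c1) in enumerate(cols):
        stage_of_point[c0 + 1:c1 + 1] = s
    rows = []
    for t in range(traces.n_traj):
        for j, x in enumerate(traces.coordinates):
            rows.append((t, int(stage_of_point[j]), x, traces.traces[t, j]))
    df = pd.DataFrame(rows, columns=["traj_id", "stage", "coordinate", "cumulative_work"])
    df.to_csv(path, index=False, float_format="%.8g")


def read_work_csv(path: str | Path, temperature: float) -> WorkTraces:
    """Read long-form work traces; stage breakpoints inferred from the stage column."""
    df = pd.read_csv(path)
    needed = {"traj_id", "stage", "coordinate", "cumulative_work"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: work CSV needs columns {sorted(needed)}")
    coords = np.array(sorted(df["coordinate"].unique()))
    traj_ids = sorted(df["traj_id"].unique())
    traces = np.full((len(traj_ids), len(coords)), np.nan)
    cidx = {c: j for j, c in enumerate(coords)}
    tidx = {t: i for i, t in enumerate(traj_ids)}
    for t, x, w in zip(df["traj_id"], df["coordinate"], df["cumulative_work"]):
        traces[tidx[t], cidx[x]] = w
    if np.isnan(traces).any():
        raise FormatError(f"{path}: ragged work table (missing coordinate points)")
    # breakpoints: first coordinate, then the last coordinate of every stage
    stage_last = df.groupby("stage")["coordinate"].max().sort_index().to_numpy()
    stages = np.concatenate(([coords[0]], stage_last))
    return WorkTraces(stages, coords, traces, temperature)
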