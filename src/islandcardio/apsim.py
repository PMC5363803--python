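"""Heterogeneous coupled-oscillator simulation of cardiomyocyte islands.

Each cell of a rectangular lattice follows the two-variable Aliev-Panfilov
excitable-cell model with a static per-cell leak (drive) current drawn from
a Gaussian, which gives every cell its own intrinsic spontaneous beat rate.
Nearest-neighbour electrotonic coupling of strength ``phi`` ties the lattice
into a syncytium:

    du_ij/dt = k u_ij (1 - u_ij)(u_ij - a) - u_ij v_ij + c_ij + phi * L[u]_ij
    dv_ij/dt = eps(u_ij) (k u_ij - v_ij)

with a step recovery rate eps(u) (fast below the excitation threshold,
slow above) and L the 4-neighbour lattice Laplacian with no-flux edges.

The module provides single-island simulation with beat-period read-out from
the lattice-mean intensity trace I(t) = <u_ij(t)>, a replicated sweep over
island sizes, the "fastest cell" extreme-value null model (island rate set
by the quickest intrinsic pacemaker it happens to contain), and conduction
velocity measurement / coupling-constant calibration on a strip geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._bs23 import STATUS_OK, integrate_bs23

__all__ = [
    "APParams",
    "LatticeState",
    "SimResult",
    "ConductionMeasurement",
    "ap_rhs",
    "sample_leak",
    "simulate_island",
    "simulate_batch",
    "beat_period",
    "trace_peak_times",
    "size_sweep",
    "intrinsic_periods",
    "fastest_cell_null",
    "conduction_velocity",
    "calibrate_phi",
    "SimulationError",
    "MeasurementError",
    "CalibrationError",
]


class SimulationError(RuntimeError):
    pass


class MeasurementError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class APParams:
    """Aliev-Panfilov lattice parameters (dimensionless model units)."""

    k: float = 10.0            # reaction rate constant
    a: float = 0.05            # excitation threshold
    phi: float = 400.0         # nearest-neighbour coupling
    eps_low: float = 1.0       # recovery rate for u <= u_switch
    eps_high: float = 0.1      # recovery rate for u > u_switch
    u_switch: float = 0.05
    c_mean: float = 0.09       # mean leak (drive) current per cell
    c_cv: float = 0.22         # coefficient of variation of the leak
    t_span: tuple[float, float] = (0.0, 120.0)
    boundary: str = "noflux"   # "noflux" (mirrored) or "truncate"
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not 0 < self.a < 1:
            raise ValueError("a must lie in (0, 1)")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if self.c_cv < 0:
            raise ValueError("c_cv must be non-negative")
        if not self.t_span[1] > self.t_span[0]:
            raise ValueError("t_span must be increasing")
        if self.boundary not in ("noflux", "truncate"):
            raise ValueError("boundary must be 'noflux' or 'truncate'")


@dataclass
class LatticeState:
    """Excitation u, recovery v, and static leak c matrices of one lattice."""

    u: np.ndarray
    v: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if not (self.u.shape == self.v.shape == self.c.shape):
            raise ValueError("u, v, c must share a shape")
        for name, arr in (("u", self.u), ("v", self.v), ("c", self.c)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


@dataclass
class SimResult:
    """Trajectory of one island: mean-field trace and optional cell traces."""

    times: np.ndarray
    I: np.ndarray
    c: np.ndarray
    u_traces: np.ndarray | None = None
    v_traces: np.ndarray | None = None
    peak_times: np.ndarray | None = None
    beat_period: float = np.nan


@dataclass
class ConductionMeasurement:
    velocity_cells_per_time: float
    arrival_times: np.ndarray
    columns: np.ndarray
    r_squared: float
    ap_duration: float
    velocity_mm_per_s: float = np.nan
    wavelength_mm: float = np.nan


def ap_rhs(state: LatticeState, params: APParams) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand sides (du/dt, dv/dt) for a lattice state.

    Reference vectorized implementation; the integrator uses an equivalent
    jitted kernel.  With no-flux edges a spatially uniform lattice has zero
    coupling term everywhere.
    """
    u, v, c = state.u, state.v, state.c
    if params.boundary == "noflux":
        up = np.pad(u, 1, mode="edge")
        lap = (up[2:, 1:-1] + up[:-2, 1:-1] + up[1:-1, 2:] + up[1:-1, :-2] - 4 * u)
    else:
        up = np.pad(u, 1, mode="constant")
        lap = (up[2:, 1:-1] + up[:-2, 1:-1] + up[1:-1, 2:] + up[1:-1, :-2] - 4 * u)
    du = params.k * u * (1 - u) * (u - params.a) - u * v + c + params.phi * lap
    eps = np.where(u <= params.u_switch, params.eps_low, params.eps_high)
    dv = eps * (params.k * u - v)
    return du, dv


def sample_leak(rows: int, cols: int, c_mean: float = 0.09, c_cv: float = 0.22,
                seed=None) -> np.ndarray:
    """Draw the static per-cell leak matrix c_ij ~ N(c_mean, c_cv*c_mean).

    Truncated at zero: a negative leak would be an unphysical sink, and at
    the default 22% CV negatives have probability ~3e-6 per cell.
    """
    if c_mean <= 0:
        raise ValueError("c_mean must be positive")
    if c_cv < 0:
        raise ValueError("c_cv must be non-negative")
    rng = np.random.default_rng(seed)
    c = rng.normal(c_mean, c_cv * c_mean, size=(rows, cols))
    return np.clip(c, 0.0, None)


def simulate_batch(c_batch: np.ndarray, params: APParams, *, dt_out: float = 0.02,
                   store_fields: bool = False, u0: np.ndarray | None = None,
                   v0: np.ndarray | None = None,
                   t_span: tuple[float, float] | None = None):
    """Integrate a batch of lattices sharing parameters but distinct leaks.

    Returns (times, I, U, V) with I of shape (T, B) and U/V of shape
    (T, B, rows, cols) when ``store_fields`` (else None).
    """
    c_batch = np.ascontiguousarray(c_batch, dtype=float)
    if c_batch.ndim != 3:
        raise ValueError("c_batch must have shape (batch, rows, cols)")
    t0, t1 = t_span if t_span is not None else params.t_span
    t_out = np.arange(t0, t1 + dt_out / 2, dt_out)
    u0 = np.zeros_like(c_batch) if u0 is None else np.ascontiguousarray(u0, dtype=float)
    v0 = np.zeros_like(c_batch) if v0 is None else np.ascontiguousarray(v0, dtype=float)
    status, I, U, V, n_steps, n_rej = integrate_bs23(
        u0, v0, c_batch, params.k, params.a, params.phi, params.eps_low,
        params.eps_high, params.u_switch, params.boundary == "noflux",
        t0, t1, params.rtol, params.atol, t_out, store_fields)
    if status != STATUS_OK:
        raise SimulationError(
            f"step size underflow after {n_steps} steps ({n_rej} rejected); "
            f"lattice {c_batch.shape}, phi={params.phi}")
    if not store_fields:
        U = V = None
    return t_out, I, U, V


def simulate_island(rows: int, cols: int, params: APParams = APParams(), seed=None,
                    *, c: np.ndarray | None = None, dt_out: float = 0.02,
                    store_fields: bool = False) -> SimResult:
    """Simulate one island from rest (u = v = 0) over params.t_span.

    The leak matrix is sampled from the seed unless given explicitly.
    Returns the mean-field intensity trace I(t) = <u_ij(t)> sampled on a
    uniform grid, with per-cell traces when ``store_fields``.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if c is None:
        c = sample_leak(rows, cols, params.c_mean, params.c_cv, seed)
    c = np.asarray(c, dtype=float)
    if c.shape != (rows, cols):
        raise ValueError("c has wrong shape")
    times, I, U, V = simulate_batch(c[None], params, dt_out=dt_out,
                                    store_fields=store_fields)
    res = SimResult(times=times, I=I[:, 0], c=c,
                    u_traces=U[:, 0] if U is not None else None,
                    v_traces=V[:, 0] if V is not None else None)
    return res


# ---------------------------------------------------------------------------
# beat-period extraction

def trace_peak_times(times: np.ndarray, trace: np.ndarray, *,
                     discard_frac: float = 0.2,
                     height_frac: float = 0.5) -> np.ndarray:
    """Peak times of an oscillatory trace, with sub-sample refinement.

    The first ``discard_frac`` of the record is dropped to skip the
    start-up transient.  Peaks are local maxima above ``height_frac`` of
    the trace range, separated by at least a quarter of the running period
    estimate; peak times are refined by a parabolic fit through the three
    samples around each maximum.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    t0 = times[0] + discard_frac * (times[-1] - times[0])
    sel = times >= t0
    t, y = times[sel], trace[sel]
    if y.size < 3:
        return np.empty(0)
    rng = y.max() - y.min()
    if rng <= 0:
        return np.empty(0)
    height = y.min() + height_frac * rng
    idx, _ = find_peaks(y, height=height)
    if idx.size >= 2:
        est = np.median(np.diff(t[idx]))
        dt = t[1] - t[0]
        dist = max(1, int(round(0.25 * est / dt)))
        idx, _ = find_peaks(y, height=height, distance=dist)
    # parabolic sub-sample refinement
    out = []
    for i in idx:
        if 0 < i < y.size - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            out.append(t[i] + shift * (t[1] - t[0]))
        else:
            out.append(t[i])
    return np.asarray(out)


def beat_period(result: SimResult, **kwargs) -> float:
    """Beat period from the interval between the last two peaks of I(t).

    Returns NaN (flagged, not raised) when fewer than two peaks exist.
    Stores peak times and the period on the result.
    """
    pk = trace_peak_times(result.times, result.I, **kwargs)
    result.peak_times = pk
    result.beat_period = float(pk[-1] - pk[-2]) if pk.size >= 2 else np.nan
    return result.beat_period


# ---------------------------------------------------------------------------
# island-size sweep and the fastest-cell null

def size_sweep(sizes=(1, 2, 4, 8, 12, 16), n_reps: int = 52,
               params: APParams = APParams(), seed=None,
               dt_out: float = 0.02) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated simulation of square islands of several sizes.

    Each size is simulated ``n_reps`` times with the leak matrix resampled
    per replicate.  Returns (per_rep, summary): per_rep has one row per
    (size, rep) with the beat period; summary has per-size mean, std and
    the count of replicates with a defined period.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        c_batch = np.clip(
            rng.normal(params.c_mean, params.c_cv * params.c_mean, size=(n_reps, n, n)),
            0.0, None)
        times, I, _, _ = simulate_batch(c_batch, params, dt_out=dt_out)
        for rep in range(n_reps):
            res = SimResult(times=times, I=I[:, rep], c=c_batch[rep])
            per = beat_period(res)
            rows.append({"size": n, "rep": rep, "period": per})
    per_rep = pd.DataFrame(rows)
    summary = (per_rep.groupby("size")["period"]
               .agg(mean="mean", std="std", n_defined=lambda s: int(s.notna().sum()))
               .reset_index())
    return per_rep, summary


def intrinsic_periods(n_cells: int, params: APParams = APParams(), seed=None,
                      c_values: np.ndarray | None = None) -> np.ndarray:
    """Intrinsic (uncoupled) beat periods of single cells with sampled leaks."""
    if c_values is None:
        c_values = sample_leak(n_cells, 1, params.c_mean, params.c_cv, seed).ravel()
    c_batch = np.asarray(c_values, dtype=float).reshape(-1, 1, 1)
    single = replace(params, phi=0.0)
    times, I, _, _ = simulate_batch(c_batch, single, dt_out=0.02)
    periods = np.empty(c_batch.shape[0])
    for b in range(c_batch.shape[0]):
        pk = trace_peak_times(times, I[:, b])
        periods[b] = pk[-1] - pk[-2] if pk.size >= 2 else np.nan
    return periods


def fastest_cell_null(sizes=(1, 2, 4, 8, 12, 16), n_reps: int = 52,
                      period_distribution=None, seed=None) -> pd.DataFrame:
    """Extreme-value null: the island period is the minimum of N = size^2
    i.i.d. intrinsic periods (the fastest pacemaker wins).

    ``period_distribution`` is either a 1-D array of intrinsic periods to
    resample from, or a callable ``f(rng, n) -> array``.  Returns per-size
    Monte-Carlo mean and std of the island period.
    """
    rng = np.random.default_rng(seed)
    if period_distribution is None:
        raise ValueError("period_distribution is required (array or callable)")
    if callable(period_distribution):
        draw = period_distribution
    else:
        pool = np.asarray(period_distribution, dtype=float)
        pool = pool[np.isfinite(pool)]
        if pool.size == 0 or np.any(pool <= 0):
            raise ValueError("period distribution must be positive-valued")
        def draw(r, n):
            return r.choice(pool, size=n, replace=True)
    rows = []
    for n in sizes:
        N = n * n
        mins = draw(rng, (n_reps, N)).min(axis=1)
        rows.append({"size": n, "mean": float(mins.mean()),
                     "std": float(mins.std(ddof=1)) if n_reps > 1 else 0.0,
                     "n": n_reps})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conduction velocity and coupling calibration

def conduction_velocity(strip_rows: int = 3, strip_cols: int | None = None,
                        params: APParams = APParams(), *,
                        stim_cols: int | None = None,
                        exclude_cols: int | None = None,
                        t_max: float | None = None, dt_out: float = 0.002,
                        cell_pitch_um: float = 62.5,
                        time_unit_s: float | None = None) -> ConductionMeasurement:
    """Propagation speed of a stimulated wave along a quiescent strip.

    The strip has zero leak (quiescent excitable medium); the first
    ``stim_cols`` columns start excited (u = 1).  The half-max arrival
    time of the column-mean excitation is fitted against column index;
    the velocity is the inverse slope, in cells per model time unit.
    Geometry defaults scale with the diffusion length sqrt(phi/k): the
    strip is ~14 diffusion lengths long and measurement starts 3 lengths
    past the stimulus, so the fit sees a fully developed front.  Physical
    units follow from ``cell_pitch_um`` (default 62.5 um, one cell pitch
    when 16 cells span a 1 mm island) and a user-supplied
    seconds-per-time-unit calibration.
    """
    ell = max(1.0, np.sqrt(max(params.phi, 1e-12) / params.k))
    if stim_cols is None:
        stim_cols = max(3, int(round(2 * ell)))
    if exclude_cols is None:
        exclude_cols = max(10, int(round(3 * ell)))
    if strip_cols is None:
        strip_cols = stim_cols + exclude_cols + int(round(10 * ell)) + 5
    if t_max is None:
        v_est = 0.5 * np.sqrt(params.k * max(params.phi, 1.0))
        t_max = 2.0 + 1.5 * strip_cols / v_est
    if strip_cols - stim_cols - exclude_cols < 5:
        raise ValueError("strip too short for >= 5 measurement columns")
    c = np.zeros((1, strip_rows, strip_cols))
    u0 = np.zeros_like(c)
    u0[:, :, :stim_cols] = 1.0
    times, I, U, _ = simulate_batch(c, params, dt_out=dt_out, store_fields=True,
                                    u0=u0, t_span=(0.0, t_max))
    col_mean = U[:, 0].mean(axis=1)        # (T, cols)
    far_margin = max(1, int(round(ell)))
    cols = np.arange(stim_cols + exclude_cols, strip_cols - far_margin)
    umax = col_mean[:, cols].max(axis=0)
    if np.any(umax < 0.3):
        raise MeasurementError("no propagating wave reached the measurement zone")
    arrivals = np.empty(cols.size)
    for m, j in enumerate(cols):
        tr = col_mean[:, j]
        half = 0.5 * tr.max()
        i = int(np.argmax(tr >= half))
        if i == 0:
            arrivals[m] = times[0]
        else:
            f = (half - tr[i - 1]) / (tr[i] - tr[i - 1])
            arrivals[m] = times[i - 1] + f * (times[i] - times[i - 1])
    slope, intercept = np.polyfit(cols, arrivals, 1)
    pred = slope * cols + intercept
    ss_res = float(np.sum((arrivals - pred) ** 2))
    ss_tot = float(np.sum((arrivals - arrivals.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope <= 0:
        raise MeasurementError("arrival times do not increase along the strip")
    vel = 1.0 / slope
    # AP duration above half-max at a middle column, for the wavelength
    jmid = cols[cols.size // 2]
    tr = col_mean[:, jmid]
    above = tr >= 0.5 * tr.max()
    apd = float(np.count_nonzero(above) * dt_out)
    meas = ConductionMeasurement(velocity_cells_per_time=float(vel),
                                 arrival_times=arrivals, columns=cols,
                                 r_squared=r2, ap_duration=apd)
    if time_unit_s is not None:
        v_mm_s = vel * (cell_pitch_um / 1000.0) / time_unit_s
        meas.velocity_mm_per_s = v_mm_s
        meas.wavelength_mm = v_mm_s * apd * time_unit_s
    return meas


def calibrate_phi(target_velocity_cells_per_time: float,
                  params: APParams = APParams(), *,
                  phi_lo: float = 1.0, phi_hi: float = 6400.0,
                  rel_tol: float = 0.05, max_iter: int = 40,
                  **cv_kwargs) -> tuple[float, float]:
    """Bisection on phi until the simulated conduction velocity matches.

    The wave speed grows like sqrt(phi) (diffusive scaling), so velocity
    is monotone in phi and bisection in log-phi converges.  Returns
    (phi, achieved velocity); raises CalibrationError if the search range
    does not bracket the target.
    """
    if target_velocity_cells_per_time <= 0:
        raise ValueError("target velocity must be positive")

    def vel(phi):
        p = replace(params, phi=phi)
        return conduction_velocity(params=p, **cv_kwargs).velocity_cells_per_time

    v_lo, v_hi = vel(phi_lo), vel(phi_hi)
    tgt = target_velocity_cells_per_time
    if not (v_lo <= tgt <= v_hi):
        raise CalibrationError(
            f"target {tgt:.3g} outside bracket [{v_lo:.3g}, {v_hi:.3g}] "
            f"for phi in [{phi_lo}, {phi_hi}]")
    lo, hi = np.log(phi_lo), np.log(phi_hi)
    phi = np.exp(0.5 * (lo + hi))
    v = vel(phi)
    for _ in range(max_iter):
        if abs(v - tgt) <= rel_tol * tgt:
            break
        if v < tgt:
            lo = np.log(phi)
        else:
            hi = np.log(phi)
        phi = np.exp(0.5 * (lo + hi))
        v = vel(phi)
    return float(phi), float(v)
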