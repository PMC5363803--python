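"""Ground-truthed synthetic inputs: waveforms, fluorescence movies, TPM matrices.

Everything the analysis modules consume can be generated here with the
generating parameters recorded, so that recovery error can be measured
exactly.  Movies emulate wide-field optical electrophysiology recordings:
islands of known dF/F waveforms sitting on a bright autofluorescent
background that photobleaches exponentially, with camera-like Gaussian
noise and static bright aggregates that are insensitive to the signal.
Expression matrices emulate TPM tables for sample groups planted at known
positions along a developmental (progenitor -> adult) axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .geometry import IslandLayout, make_masks

__all__ = [
    "WaveformSpec",
    "MovieSpec",
    "Aggregate",
    "GroundTruth",
    "make_waveform",
    "pulse_template",
    "render_movie",
    "save_movie",
    "load_movie",
    "synth_expression",
]

RISE_FRACS = {"voltage": (0.2, 0.8), "calcium": (0.3, 0.7)}


@dataclass(frozen=True)
class WaveformSpec:
    """Template dF/F waveform of one island.

    ``rise_time_s`` is the 20-80% upstroke interval for voltage and the
    30-70% interval for calcium; ``apd50_s`` is the width at half maximum
    (from the upstroke half-max crossing to 50% of return to baseline).
    Typical amplitudes are ~0.35 dF/F for voltage and ~1.8 for calcium.
    """

    kind: str = "voltage"
    period_s: float = 1.0
    amplitude: float = 0.35
    apd50_s: float = 0.3
    rise_time_s: float = 0.05
    f0: float = 100.0

    def __post_init__(self):
        if self.kind not in RISE_FRACS:
            raise ValueError("kind must be 'voltage' or 'calcium'")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not (0 < self.rise_time_s < self.apd50_s < self.period_s):
            raise ValueError("need 0 < rise_time < apd50 < period")
        if self.f0 <= 0:
            raise ValueError("baseline f0 must be positive")


def _measure_pulse(t: np.ndarray, y: np.ndarray, kind: str) -> dict:
    """Waveform parameters of a single unit-baseline pulse on a dense grid."""
    peak = float(y.max())
    ip = int(np.argmax(y))

    def crossing(level, lo, hi, rising):
        seg_t, seg_y = t[lo:hi], y[lo:hi]
        if rising:
            idx = np.flatnonzero((seg_y[:-1] < level) & (seg_y[1:] >= level))
        else:
            idx = np.flatnonzero((seg_y[:-1] >= level) & (seg_y[1:] < level))
        if idx.size == 0:
            return np.nan
        i = idx[0] if rising else idx[-1]
        f = (level - seg_y[i]) / (seg_y[i + 1] - seg_y[i])
        return float(seg_t[i] + f * (seg_t[i + 1] - seg_t[i]))

    lo_f, hi_f = RISE_FRACS[kind]
    t_up50 = crossing(0.5 * peak, 0, ip + 1, True)
    rise = crossing(hi_f * peak, 0, ip + 1, True) - crossing(lo_f * peak, 0, ip + 1, True)
    widths = {}
    for frac, name in ((0.7, "apd30"), (0.5, "apd50"), (0.3, "apd70")):
        widths[name] = crossing(frac * peak, ip, y.size, False) - t_up50
    rate = float(np.max(np.diff(y) / np.diff(t)))
    return {"amplitude": peak, "t_up50": t_up50, "rise_time": float(rise),
            "max_upstroke_rate": rate, **widths}


def pulse_template(spec: WaveformSpec, n_dense: int = 40001):
    """Calibrated single-period pulse: (t_dense, y_dense, truth dict).

    The pulse is a product of a sigmoidal upstroke and a sigmoidal decay,
    baseline-subtracted and scaled to the requested amplitude.  The two
    free time constants are calibrated numerically so the measured rise
    time and width-at-half-max match the spec (well inside 1%).
    """
    lo_f, hi_f = RISE_FRACS[spec.kind]
    log_ratio = np.log(hi_f / (1 - hi_f)) - np.log(lo_f / (1 - lo_f))
    tau_r = spec.rise_time_s / log_ratio
    tau_f = spec.apd50_s / 8.0
    t_f0 = spec.apd50_s
    t = np.linspace(0.0, spec.period_s, n_dense)

    def build(tau_r, t_f0):
        t_r0 = 6.0 * tau_r
        g = 1.0 / (1.0 + np.exp(-(t - t_r0) / tau_r))
        g *= 1.0 / (1.0 + np.exp((t - t_r0 - t_f0) / tau_f))
        g -= g.min()
        m = g.max()
        return g / m if m > 0 else g

    for _ in range(30):
        y = build(tau_r, t_f0)
        meas = _measure_pulse(t, y, spec.kind)
        err_r = meas["rise_time"] - spec.rise_time_s
        err_w = meas["apd50"] - spec.apd50_s
        if abs(err_r) < 1e-4 * spec.rise_time_s and abs(err_w) < 1e-4 * spec.apd50_s:
            break
        tau_r *= spec.rise_time_s / meas["rise_time"]
        t_f0 -= err_w
    y = build(tau_r, t_f0) * spec.amplitude
    truth = _measure_pulse(t, build(tau_r, t_f0), spec.kind)
    truth["amplitude"] = spec.amplitude
    truth["max_upstroke_rate"] *= spec.amplitude
    truth["period"] = spec.period_s
    return t, y, truth


def make_waveform(spec: WaveformSpec, times: np.ndarray, phase_s: float = 0.0) -> np.ndarray:
    """Periodic dF/F trace sampled at ``times`` (pulse onset shifted by phase)."""
    if spec.amplitude == 0:
        return np.zeros_like(np.asarray(times, dtype=float))
    t_dense, y_dense, _ = pulse_template(spec)
    tau = np.mod(np.asarray(times, dtype=float) - phase_s, spec.period_s)
    return np.interp(tau, t_dense, y_dense)


@dataclass(frozen=True)
class Aggregate:
    """Static bright fluorescent blob insensitive to the signal.

    The blob occludes the cells underneath: where its Gaussian weight w is
    high the pixel shows static brightness instead of the modulated
    reporter signal, emulating debris that is bright but voltage/calcium
    insensitive.
    """

    x_um: float
    y_um: float
    brightness: float = 400.0
    sigma_um: float = 8.0


@dataclass
class MovieSpec:
    """Rendering recipe for one single-channel fluorescence movie."""

    layout: IslandLayout
    waveform: WaveformSpec | dict = field(default_factory=WaveformSpec)
    frame_rate_hz: float = 500.0
    duration_s: float = 20.0
    background_level: float = 200.0
    bleach_tau_s: float = 100.0
    noise_sd: float = 2.0
    aggregates: tuple = ()
    period_jitter_cv: float = 0.05
    random_phase: bool = True
    seed: int | None = None

    def __post_init__(self):
        # the >= 3 beat periods requirement is enforced per island at render
        # time, where jittered periods are known
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration and frame rate must be positive")


@dataclass
class GroundTruth:
    """Generating parameters of a rendered movie, one beat-table row per beat."""

    beats: pd.DataFrame
    islands: pd.DataFrame
    responsive_mask: np.ndarray
    labels: np.ndarray
    spec: MovieSpec


def render_movie(spec: MovieSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a movie stack (T, H, W) float32 plus its ground truth.

    Pixel model: background*exp(-t/tau_bleach) everywhere, plus
    f0*(1 + dFF_k(t)) on the pixels of island k, plus static Gaussian
    aggregates, plus i.i.d. Gaussian noise.  Fully reproducible from the
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels, _ = make_masks(spec.layout)
    H, W = labels.shape
    n_frames = int(round(spec.frame_rate_hz * spec.duration_s))
    times = np.arange(n_frames) / spec.frame_rate_hz
    px = spec.layout.pixel_size_um

    movie = np.empty((n_frames, H, W), dtype=np.float32)
    bleach = spec.background_level * np.exp(-times / spec.bleach_tau_s) \
        if spec.bleach_tau_s > 0 else np.full_like(times, spec.background_level)
    movie[:] = bleach[:, None, None].astype(np.float32)

    static = np.zeros((H, W), dtype=np.float32)
    occlusion = np.zeros((H, W), dtype=np.float32)
    for ag in spec.aggregates:
        yy, xx = np.mgrid[0:H, 0:W]
        d2 = ((xx + 0.5) * px - ag.x_um) ** 2 + ((yy + 0.5) * px - ag.y_um) ** 2
        w = np.exp(-d2 / (2 * ag.sigma_um ** 2)).astype(np.float32)
        static += ag.brightness * w
        occlusion = np.maximum(occlusion, w)
    movie += static[None]

    island_ids = [int(k) for k in np.unique(labels) if k != 0]
    beat_rows, island_rows = [], []
    for k in island_ids:
        wf = spec.waveform[k] if isinstance(spec.waveform, dict) else spec.waveform
        period = wf.period_s * (1.0 + spec.period_jitter_cv * rng.standard_normal())
        period = max(period, 2.5 * wf.apd50_s)
        wfk = WaveformSpec(kind=wf.kind, period_s=period, amplitude=wf.amplitude,
                           apd50_s=wf.apd50_s, rise_time_s=wf.rise_time_s, f0=wf.f0)
        phase = rng.uniform(0, period) if spec.random_phase else 0.0
        if spec.duration_s < 3 * period:
            raise ValueError(f"island {k}: movie shorter than 3 beat periods")
        t_dense, y_dense, truth = pulse_template(wfk)
        dff = np.interp(np.mod(times - phase, period), t_dense, y_dense)
        mask = labels == k
        transmitted = (1.0 - occlusion[mask]).astype(np.float32)
        movie[:, mask] += (wfk.f0 * (1.0 + dff)).astype(np.float32)[:, None] * transmitted[None, :]
        island_rows.append({"island_id": k, "period": period, "phase": phase,
                            "f0": wfk.f0, "kind": wfk.kind, **truth})
        # one row per complete beat within the record
        m = 0
        while True:
            t_up = phase + truth["t_up50"] + m * period
            if t_up + truth["apd70"] > spec.duration_s:
                break
            if t_up >= 0:
                beat_rows.append({"island_id": k, "beat_index": m,
                                  "upstroke_time": t_up, **{kk: truth[kk] for kk in
                                  ("amplitude", "apd30", "apd50", "apd70",
                                   "rise_time", "max_upstroke_rate")},
                                  "period": period, "channel": wfk.kind})
            m += 1

    if spec.noise_sd > 0:
        movie += rng.normal(0.0, spec.noise_sd, size=movie.shape).astype(np.float32)

    truth = GroundTruth(beats=pd.DataFrame(beat_rows),
                        islands=pd.DataFrame(island_rows),
                        responsive_mask=(labels > 0) & (occlusion < 0.5),
                        labels=labels, spec=spec)
    return movie, truth


def save_movie(path, movie: np.ndarray, truth: GroundTruth | None = None) -> None:
    """Write a movie as multi-page 16-bit TIFF (+ sidecar JSON ground truth)."""
    stack = np.clip(np.round(movie), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stack)
    if truth is not None:
        side = {
            "islands": truth.islands.to_dict(orient="records"),
            "beats": truth.beats.to_dict(orient="records"),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(side, fh, indent=1)


def load_movie(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


# ---------------------------------------------------------------------------
# expression matrices

DEFAULT_GROUP_SIZES = {"CP": 4, "Adult-CM": 4, "small": 10, "confluent": 11}
DEFAULT_GROUP_POSITIONS = {"CP": 0.0, "Adult-CM": 1.0, "small": 0.50, "confluent": 0.547}


def synth_expression(n_genes: int = 6328, samples_per_group: dict | None = None,
                     group_positions: dict | None = None,
                     axis_effect_log2fc_sd: float = 1.0, noise_sd: float = 0.15,
                     baseline_mean: float = 5.0, baseline_sd: float = 2.0,
                     subset_size: int = 0, subset_positions: dict | None = None,
                     normalize: bool = True, seed=None):
    """Synthesize a gene x sample TPM matrix with planted axis positions.

    Each gene gets a baseline log2 expression and an axis loading
    ~ N(0, axis_effect_log2fc_sd); a sample of a group at position p takes
    value baseline + p*loading + N(0, noise_sd) in log2 space.  When
    ``subset_size`` > 0, the first genes form a designated subset whose
    positions may differ per group (``subset_positions``), emulating a
    small gene set that responds to culture geometry far more than the
    genome-wide average.  TPM columns are renormalized to sum 1e6 unless
    ``normalize`` is False (renormalization after planting, so expression
    filters behave as with real TPM).

    Returns (tpm DataFrame, truth dict with groups/positions/loadings).
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    sizes = dict(DEFAULT_GROUP_SIZES if samples_per_group is None else samples_per_group)
    positions = dict(DEFAULT_GROUP_POSITIONS if group_positions is None else group_positions)
    for g, p in positions.items():
        if not -0.5 <= p <= 1.5:
            raise ValueError(f"group {g}: position {p} outside [-0.5, 1.5]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    if normalize:
        # anchor the library: shift baselines so a noiseless library sums
        # to exactly 1e6 TPM, making the final renormalization a near
        # no-op instead of a geometry-warping rescale
        baseline += np.log2((1e6 + n_genes) / np.exp2(baseline).sum())
    loading = rng.normal(0.0, axis_effect_log2fc_sd, n_genes)
    if normalize:
        # TPM anchors cannot differ in total output, so a well-defined
        # plant needs the position-0 and position-1 profiles to have equal
        # library size: shift the loadings accordingly
        loading -= np.log2(np.exp2(baseline + loading).sum() / np.exp2(baseline).sum())

    cols, groups = [], []
    data = {}
    s0 = float(np.exp2(baseline).sum())
    for g, n in sizes.items():
        p_main = positions[g]
        pos_vec = np.full(n_genes, p_main)
        if subset_size and subset_positions and g in subset_positions:
            pos_vec[:subset_size] = subset_positions[g]
        x_clean = baseline + pos_vec * loading
        if normalize:
            # closure centering: shift each group's noiseless profile so
            # total output is position-independent; TPM normalization
            # removes library size, so a meaningful planted position must
            # not be confounded with it
            x_clean = x_clean - np.log2(np.exp2(x_clean).sum() / s0)
        for i in range(n):
            name = f"{g}_{i+1}"
            x = x_clean
            if noise_sd > 0:
                x = x + rng.normal(0.0, noise_sd, n_genes)
            data[name] = np.maximum(np.exp2(x) - 1.0, 0.0)
            cols.append(name)
            groups.append(g)
    tpm = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    if normalize:
        tpm = tpm * (1e6 / tpm.sum(axis=0))
    truth = {
        "groups": pd.Series(groups, index=cols, name="group"),
        "positions": positions,
        "subset_positions": dict(subset_positions or {}),
        "subset_genes": genes[:subset_size],
        "baseline_log2": pd.Series(baseline, index=genes),
        "loading_log2fc": pd.Series(loading, index=genes),
        "noise_sd": noise_sd,
    }
    return tpm, truth
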