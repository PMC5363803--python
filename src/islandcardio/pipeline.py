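"""Movie-to-parameters analysis for optical voltage/calcium recordings.

Converts raw fluorescence movie stacks of micropatterned islands into
per-beat waveform parameters: morphological background estimation, island
QC, background-subtracted island traces, sliding-minimum photobleach
correction, Schmitt-trigger spike detection, per-beat parameterization
(amplitude, widths at 30/50/70% of return to baseline, rise time, maximum
upstroke rate), correlation-based pixel weighting with per-pixel
sensitivity maps, and aggregation of parameters by island size.  Every
step runs from one configuration with no per-island intervention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.stats import ttest_ind
from skimage.morphology import opening, ellipse

from .geometry import subdivide_mask
from .synth import RISE_FRACS

__all__ = [
    "IslandTrace",
    "SensitivityMaps",
    "estimate_background",
    "qc_islands",
    "surround_mask",
    "island_trace",
    "baseline_correct",
    "detect_spikes",
    "parameterize_beats",
    "pixel_weighting",
    "amplitude_statistics",
    "aggregate_by_size",
    "analyze_movie",
    "subdivision_control",
]

BEAT_PARAMS = ["amplitude", "apd30", "apd50", "apd70", "rise_time", "max_upstroke_rate"]


@dataclass
class IslandTrace:
    """Background-subtracted fluorescence and dF/F trace of one island."""

    island_id: int
    times: np.ndarray
    F: np.ndarray
    dff: np.ndarray
    baseline: np.ndarray


@dataclass
class SensitivityMaps:
    """Pixel-resolved response maps of one island (NaN off-island)."""

    mean_image: np.ndarray
    correlation_image: np.ndarray
    sensitivity_image: np.ndarray
    per_pixel_dff: np.ndarray          # 1-D, one value per on-island pixel
    per_pixel_dff_image: np.ndarray
    weights: np.ndarray                # 1-D, clipped correlations


def estimate_background(reference_image: np.ndarray, island_size_um: float,
                        pixel_size_um: float, width_factor: float = 1.2,
                        height_um: float = 200.0) -> np.ndarray:
    """Morphological background via grayscale opening.

    The structuring element is an ellipse slightly wider than the island
    (``width_factor`` x island size) and 200 um tall, so islands are
    removed while smooth background structure survives.  Opening is
    anti-extensive (background <= input) and idempotent.
    """
    img = np.asarray(reference_image, dtype=float)
    rw = max(1, int(round(0.5 * width_factor * island_size_um / pixel_size_um)))
    rh = max(1, int(round(0.5 * height_um / pixel_size_um)))
    if 2 * rh + 1 > img.shape[0] and 2 * rw + 1 > img.shape[1]:
        raise ValueError("structuring element larger than the frame")
    return opening(img, ellipse(rh, rw))


def surround_mask(labels: np.ndarray, island_id: int, inner_px: int = 2,
                  outer_px: int = 10) -> np.ndarray:
    """Cell-free annulus around one island, excluding every island."""
    mask = labels == island_id
    inner = ndimage.binary_dilation(mask, iterations=inner_px)
    outer = ndimage.binary_dilation(mask, iterations=outer_px)
    return outer & ~inner & (labels == 0)


def island_trace(movie: np.ndarray, island_mask: np.ndarray,
                 surround: np.ndarray | None = None, *,
                 frame_rate_hz: float, island_id: int = 0,
                 reference_background: np.ndarray | None = None) -> IslandTrace:
    """Flat-average island fluorescence minus the surround background trace.

    The surround trace (mean over a cell-free annulus) captures the
    time-varying autofluorescent background, which dominates photobleach
    drift.  With an empty surround the static opening-based background is
    subtracted instead (with a warning).
    """
    island_mask = np.asarray(island_mask) > 0
    if surround is not None and island_mask.ndim == surround.ndim and \
            np.any(island_mask & (np.asarray(surround) > 0)):
        raise ValueError("island and surround masks must be disjoint")
    F = movie[:, island_mask].mean(axis=1, dtype=np.float64)
    if surround is not None and np.asarray(surround).sum() > 0:
        F = F - movie[:, np.asarray(surround) > 0].mean(axis=1, dtype=np.float64)
    else:
        warnings.warn("empty surround; subtracting opening-based static background")
        if reference_background is None:
            raise ValueError("no surround and no reference background given")
        F = F - float(reference_background[island_mask].mean())
    times = np.arange(movie.shape[0]) / frame_rate_hz
    return IslandTrace(island_id=island_id, times=times, F=F,
                       dff=np.empty(0), baseline=np.empty(0))


def _estimate_period_samples(F: np.ndarray) -> int | None:
    """Beat period in samples from the first autocorrelation peak."""
    x = F - F.mean()
    sd = x.std()
    if sd == 0:
        return None
    acf = np.correlate(x, x, mode="full")[x.size - 1:]
    acf /= acf[0]
    idx, _ = find_peaks(acf, height=0.1)
    if idx.size == 0:
        return None
    return int(idx[0])


def baseline_correct(trace: IslandTrace, window_factor: float = 1.2,
                     smooth_frac: float = 0.05) -> IslandTrace:
    """Photobleach/baseline correction by interpolated sliding-window minima.

    The beat period is estimated from the autocorrelation of F(t); minima
    of a lightly smoothed copy are located in half-overlapping windows of
    ``window_factor`` x the period (slightly longer than one beat, so each
    window sees a diastolic interval), and the baseline is the linear
    interpolation through those minimum points.  dF/F = (F - b)/b after a
    positivity check on b.
    """
    F, times = trace.F, trace.times
    n = F.size
    per = _estimate_period_samples(F)
    win = int(round(window_factor * per)) if per else max(2, n // 3)
    win = int(np.clip(win, 2, n))
    ns = max(1, int(round(smooth_frac * win)))
    Fs = ndimage.uniform_filter1d(F, ns, mode="nearest") if ns > 1 else F

    starts = list(range(0, max(1, n - win + 1), max(1, win // 2)))
    if starts[-1] != n - win and n > win:
        starts.append(n - win)
    nodes = sorted({int(np.argmin(Fs[s:s + win])) + s for s in starts})
    baseline = np.interp(np.arange(n), nodes, Fs[nodes])
    if np.any(baseline <= 0):
        raise ValueError(f"island {trace.island_id}: non-positive baseline")
    trace.baseline = baseline
    trace.dff = (F - baseline) / baseline
    return trace


def detect_spikes(times: np.ndarray, dff: np.ndarray, hi_frac: float = 0.5,
                  lo_frac: float = 0.2, min_range: float = 0.05) -> np.ndarray:
    """Rising-edge event times via a double-threshold (Schmitt) trigger.

    An event fires when the trace rises through ``hi_frac`` of its range
    having previously been below ``lo_frac``; ripple that never dips back
    below the low threshold cannot retrigger.  A trace whose total range
    is below ``min_range`` (in dF/F) yields no events.
    """
    dff = np.asarray(dff, dtype=float)
    if not np.all(np.isfinite(dff)):
        raise ValueError("dff contains non-finite values")
    lo_v, hi_v = dff.min(), dff.max()
    rng = hi_v - lo_v
    if rng < min_range:
        return np.empty(0)
    hi = lo_v + hi_frac * rng
    lo = lo_v + lo_frac * rng
    events = []
    armed = dff[0] < lo
    for i in range(1, dff.size):
        if not armed and dff[i] < lo:
            armed = True
        elif armed and dff[i - 1] < hi <= dff[i]:
            f = (hi - dff[i - 1]) / (dff[i] - dff[i - 1])
            events.append(times[i - 1] + f * (times[i] - times[i - 1]))
            armed = False
    return np.asarray(events)


def _cross_up(t, y, level, i0, i1):
    """Interpolated time of the first upward crossing of level in [i0, i1)."""
    seg = y[i0:i1]
    idx = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    if idx.size == 0:
        return np.nan
    i = i0 + idx[0]
    f = (level - y[i]) / (y[i + 1] - y[i])
    return t[i] + f * (t[i + 1] - t[i])


def _cross_down(t, y, level, i0, i1):
    """Interpolated time of the first downward crossing of level in [i0, i1)."""
    seg = y[i0:i1]
    idx = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if idx.size == 0:
        return np.nan
    i = i0 + idx[0]
    f = (y[i] - level) / (y[i] - y[i + 1])
    return t[i] + f * (t[i + 1] - t[i])


def parameterize_beats(times: np.ndarray, dff: np.ndarray,
                       spike_times: np.ndarray, channel: str = "voltage",
                       island_id: int = 0, smooth_frames: int = 3) -> pd.DataFrame:
    """Per-beat waveform parameters from a dF/F trace and its spike times.

    Amplitude is the peak dF/F of the beat above the diastolic level (a
    low percentile of the pre-upstroke interval, robust to noise); widths
    apd30/50/70 run from the upstroke half-max crossing to 30/50/70% of
    return to baseline (levels 0.7/0.5/0.3 of peak), interpolated between
    frames; rise time is 20->80% of peak for voltage and 30->70% for
    calcium; the maximum upstroke rate is the largest 3-point central
    difference on the upstroke.  The trace is smoothed once with a
    ``smooth_frames`` moving average (symmetric, so crossing times are
    unbiased) before any measurement.  Beats truncated by the end of the
    recording are excluded.
    """
    if channel not in RISE_FRACS:
        raise ValueError("channel must be 'voltage' or 'calcium'")
    lo_f, hi_f = RISE_FRACS[channel]
    t = np.asarray(times, dtype=float)
    y = np.asarray(dff, dtype=float)
    if smooth_frames > 1:
        y = ndimage.uniform_filter1d(y, smooth_frames, mode="nearest")
    spike_times = np.asarray(spike_times, dtype=float)
    rows = []
    ev_idx = np.searchsorted(t, spike_times)
    prev_peak = 0
    for b, (t_ev, i_ev) in enumerate(zip(spike_times, ev_idx)):
        i_next = ev_idx[b + 1] if b + 1 < len(ev_idx) else y.size
        if i_ev >= i_next:
            continue
        ip = int(np.argmax(y[i_ev:i_next])) + i_ev
        peak = y[ip]
        if peak <= 0:
            continue
        i_start = int(np.argmin(y[prev_peak:ip + 1])) + prev_peak if ip > prev_peak else ip
        base = float(np.percentile(y[prev_peak:ip + 1], 10)) if ip > prev_peak else y[ip]
        amp = peak - base
        # upstroke crossings (levels measured above the local base)
        t_up50 = _cross_up(t, y, base + 0.5 * amp, i_start, ip + 1)
        t_lo = _cross_up(t, y, base + lo_f * amp, i_start, ip + 1)
        t_hi = _cross_up(t, y, base + hi_f * amp, i_start, ip + 1)
        widths = {}
        complete = True
        for name, frac in (("apd30", 0.7), ("apd50", 0.5), ("apd70", 0.3)):
            td = _cross_down(t, y, base + frac * amp, ip, i_next)
            if np.isnan(td):
                complete = False
            widths[name] = td - t_up50
        if not complete or np.isnan(t_up50) or np.isnan(t_lo) or np.isnan(t_hi):
            prev_peak = ip
            continue  # truncated or malformed beat
        # max upstroke rate: trimmed maximum (mean of the three largest
        # central differences) on the already-smoothed trace, so a single
        # noisy frame pair cannot set the rate
        seg = y[max(i_start - 1, 0):ip + 2]
        if seg.size >= 3:
            dt = t[1] - t[0]
            deriv = (seg[2:] - seg[:-2]) / (2 * dt)
            k_top = min(3, deriv.size)
            rate = float(np.sort(deriv)[-k_top:].mean())
        else:
            rate = np.nan
        rows.append({"island_id": island_id, "beat_index": b,
                     "upstroke_time": t_up50, "amplitude": float(amp),
                     **widths, "rise_time": t_hi - t_lo,
                     "max_upstroke_rate": rate, "channel": channel})
        prev_peak = ip
    return pd.DataFrame(rows, columns=["island_id", "beat_index", "upstroke_time",
                                       "amplitude", "apd30", "apd50", "apd70",
                                       "rise_time", "max_upstroke_rate", "channel"])


def pixel_weighting(movie: np.ndarray, island_mask: np.ndarray,
                    island_dff: np.ndarray) -> tuple[SensitivityMaps, np.ndarray]:
    """Correlation-weighted island trace and per-pixel sensitivity maps.

    Each on-island pixel's trace is regressed on the island dF/F pulse
    shape (normalized to unit peak): the regression slope is the pixel's
    response in counts, the Pearson correlation (clipped at zero) is its
    weight, and slope/baseline is the pixel's own dF/F amplitude.  The
    reweighted trace suppresses signal-free bright aggregates.  The movie
    should already be background-subtracted.
    """
    island_mask = np.asarray(island_mask) > 0
    pix = movie[:, island_mask].astype(float)          # (T, P)
    mu = pix.mean(axis=0)
    peak = island_dff.max()
    if peak <= 0:
        warnings.warn("island trace has no positive excursion; flat weights")
        w = np.ones(pix.shape[1])
        slope = np.zeros(pix.shape[1])
        corr = np.zeros(pix.shape[1])
    else:
        s = np.asarray(island_dff, dtype=float) / peak
        ds = s - s.mean()
        var_s = float(ds @ ds)
        dp = pix - mu
        cov = ds @ dp                                   # (P,)
        slope = cov / var_s
        sd_p = np.sqrt((dp * dp).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / (sd_p * np.sqrt(var_s))
        corr = np.nan_to_num(corr)
        w = np.clip(corr, 0.0, None)
        if w.sum() == 0:
            warnings.warn("all pixel weights zero; falling back to flat average")
            w = np.ones(pix.shape[1])
        s_mean = s.mean()
        baseline_p = mu - slope * s_mean
        with np.errstate(invalid="ignore", divide="ignore"):
            ppd = np.where(baseline_p > 0, slope / baseline_p, np.nan)

    if peak <= 0:
        ppd = np.zeros(pix.shape[1])
    reweighted = pix @ w / w.sum()

    def to_image(vals):
        img = np.full(island_mask.shape, np.nan)
        img[island_mask] = vals
        return img

    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(mu != 0, slope / mu, np.nan)
    maps = SensitivityMaps(mean_image=to_image(mu),
                           correlation_image=to_image(corr),
                           sensitivity_image=to_image(sens),
                           per_pixel_dff=ppd,
                           per_pixel_dff_image=to_image(ppd),
                           weights=w)
    return maps, reweighted


def amplitude_statistics(per_pixel_dff: np.ndarray,
                         responsive_threshold: float = 0.2,
                         bins: int = 50) -> dict:
    """Histogram of per-pixel dF/F plus the mean over responsive pixels.

    Fluorescent but unresponsive pixels (dF/F below the threshold) are
    excluded from the mean; if no pixel is responsive the mean is NaN and
    the result is flagged.
    """
    vals = np.asarray(per_pixel_dff, dtype=float)
    vals = vals[np.isfinite(vals)]
    hist, edges = np.histogram(vals, bins=bins)
    responsive = vals[vals >= responsive_threshold]
    return {
        "hist": hist, "bin_edges": edges,
        "n_pixels": int(vals.size), "n_responsive": int(responsive.size),
        "mean_responsive": float(responsive.mean()) if responsive.size else float("nan"),
        "flag_no_responsive": responsive.size == 0,
    }


def qc_islands(movies: dict[str, np.ndarray], labels: np.ndarray, *,
               frame_rate_hz: dict[str, float] | float,
               abs_threshold: float | None = None, coverage_min: float = 0.8,
               min_spikes: int = 2,
               reference_background: np.ndarray | None = None):
    """Island quality control: coverage and beating in every channel.

    An island is rejected when its fluorescent-pixel coverage (pixels of
    the time-averaged, background-subtracted image above an absolute
    threshold shared by the whole data set, Otsu-derived if not given) is
    below ``coverage_min``, or when fewer than ``min_spikes`` beats are
    detected in any channel.  Returns (accepted ids, log DataFrame).
    """
    from skimage.filters import threshold_otsu

    if not isinstance(frame_rate_hz, dict):
        frame_rate_hz = {ch: frame_rate_hz for ch in movies}
    ref_ch = next(iter(movies))
    ref = movies[ref_ch].mean(axis=0)
    bg = reference_background if reference_background is not None else np.zeros_like(ref)
    ref_sub = ref - bg
    thr = abs_threshold if abs_threshold is not None else float(threshold_otsu(ref_sub))

    ids = [int(k) for k in np.unique(labels) if k != 0]
    log, accepted = [], []
    for k in ids:
        mask = labels == k
        coverage = float((ref_sub[mask] > thr).mean())
        if coverage < coverage_min:
            log.append({"island_id": k, "accepted": False,
                        "reason": f"coverage {coverage:.2f} < {coverage_min}"})
            continue
        sur = surround_mask(labels, k)
        beating = True
        for ch, mov in movies.items():
            tr = island_trace(mov, mask, sur, frame_rate_hz=frame_rate_hz[ch],
                              island_id=k)
            tr = baseline_correct(tr)
            ev = detect_spikes(tr.times, tr.dff)
            if ev.size < min_spikes:
                beating = False
                log.append({"island_id": k, "accepted": False,
                            "reason": f"<{min_spikes} beats in {ch}"})
                break
        if beating:
            accepted.append(k)
            log.append({"island_id": k, "accepted": True, "reason": ""})
    return accepted, pd.DataFrame(log)


def analyze_movie(movie: np.ndarray, labels: np.ndarray, channel: str, *,
                  frame_rate_hz: float, island_ids=None,
                  use_pixel_weighting: bool = False,
                  window_factor: float = 1.2,
                  hi_frac: float = 0.5, lo_frac: float = 0.2,
                  min_range: float = 0.05):
    """Run the full trace pipeline on every (accepted) island of a movie.

    Returns (beat_table, traces, maps): the concatenated per-beat table,
    a dict island_id -> IslandTrace, and (when pixel weighting is on) a
    dict island_id -> SensitivityMaps.
    """
    if island_ids is None:
        island_ids = [int(k) for k in np.unique(labels) if k != 0]
    tables, traces, maps = [], {}, {}
    for k in island_ids:
        mask = labels == k
        sur = surround_mask(labels, k)
        tr = island_trace(movie, mask, sur, frame_rate_hz=frame_rate_hz, island_id=k)
        tr = baseline_correct(tr, window_factor=window_factor)
        if use_pixel_weighting:
            sur_trace = movie[:, sur].mean(axis=1) if sur.sum() else 0.0
            sub = movie - (sur_trace[:, None, None] if np.ndim(sur_trace) else sur_trace)
            mp, rew = pixel_weighting(sub, mask, tr.dff)
            maps[k] = mp
            tr2 = IslandTrace(island_id=k, times=tr.times, F=rew,
                              dff=np.empty(0), baseline=np.empty(0))
            tr = baseline_correct(tr2, window_factor=window_factor)
        ev = detect_spikes(tr.times, tr.dff, hi_frac, lo_frac, min_range)
        bt = parameterize_beats(tr.times, tr.dff, ev, channel, island_id=k)
        tables.append(bt)
        traces[k] = tr
    beat_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return beat_table, traces, maps


def island_medians(beat_table: pd.DataFrame) -> pd.DataFrame:
    """Island-level parameters: median over beats, plus the beat period."""
    rows = []
    for k, grp in beat_table.groupby("island_id"):
        row = {"island_id": k, "n_beats": len(grp)}
        for p in BEAT_PARAMS:
            row[p] = float(grp[p].median())
        ups = np.sort(grp["upstroke_time"].to_numpy())
        row["period"] = float(np.median(np.diff(ups))) if ups.size >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_size(beat_table: pd.DataFrame, island_size_labels) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-size mean and s.e.m. of each parameter, std of the beat period,
    and pairwise two-sided Welch t-tests between size groups.

    Islands are first reduced to their median over beats so that islands,
    not beats, are the statistical unit.  Sizes with a single island get
    no std (with a warning).
    """
    med = island_medians(beat_table)
    med["size"] = med["island_id"].map(dict(island_size_labels)
                                       if not isinstance(island_size_labels, pd.Series)
                                       else island_size_labels)
    params = BEAT_PARAMS + ["period"]
    rows = []
    for size, grp in med.groupby("size"):
        n = len(grp)
        if n == 1:
            warnings.warn(f"size {size}: single island, std omitted")
        row = {"size": size, "n_islands": n}
        for p in params:
            v = grp[p].to_numpy(dtype=float)
            row[f"{p}_mean"] = float(np.nanmean(v))
            row[f"{p}_sem"] = float(np.nanstd(v, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            row[f"{p}_std"] = float(np.nanstd(v, ddof=1)) if n > 1 else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)
    tests = []
    sizes = sorted(med["size"].dropna().unique())
    for i, s1 in enumerate(sizes):
        for s2 in sizes[i + 1:]:
            for p in params:
                a = med.loc[med["size"] == s1, p].dropna()
                b = med.loc[med["size"] == s2, p].dropna()
                if len(a) >= 2 and len(b) >= 2:
                    t, pv = ttest_ind(a, b, equal_var=False)
                    tests.append({"size_a": s1, "size_b": s2, "param": p,
                                  "t": float(t), "p": float(pv)})
    return summary, pd.DataFrame(tests)


def subdivision_control(movie: np.ndarray, parent_mask: np.ndarray,
                        sub_sizes_um, pixel_size_um: float, channel: str, *,
                        frame_rate_hz: float, surround: np.ndarray | None = None,
                        **pipe_kwargs) -> pd.DataFrame:
    """Analyze one large island as if cut into smaller synthetic islands.

    For each requested sub-size the parent mask is tiled, the full trace
    pipeline runs on every sub-mask, and per-parameter means across
    sub-islands are reported next to the direct full-island analysis
    (sub-size = parent edge), to confirm the analysis is unbiased with
    respect to island size.
    """
    parent_mask = np.asarray(parent_mask) > 0
    rows_px = np.flatnonzero(parent_mask.any(axis=1))
    cols_px = np.flatnonzero(parent_mask.any(axis=0))
    edge_um = max(rows_px.size, cols_px.size) * pixel_size_um

    def run_mask(mask):
        tr = island_trace(movie, mask, surround, frame_rate_hz=frame_rate_hz)
        tr = baseline_correct(tr)
        ev = detect_spikes(tr.times, tr.dff,
                           pipe_kwargs.get("hi_frac", 0.5),
                           pipe_kwargs.get("lo_frac", 0.2),
                           pipe_kwargs.get("min_range", 0.05))
        return parameterize_beats(tr.times, tr.dff, ev, channel)

    out = []
    for sub in list(sub_sizes_um) + [edge_um]:
        masks = subdivide_mask(parent_mask, sub, pixel_size_um) \
            if sub < edge_um else [parent_mask]
        vals = {p: [] for p in BEAT_PARAMS}
        n_ok = 0
        for m in masks:
            if not m.any():
                continue
            bt = run_mask(m)
            if len(bt) == 0:
                continue
            n_ok += 1
            for p in BEAT_PARAMS:
                vals[p].append(float(bt[p].median()))
        row = {"sub_size_um": float(sub), "n_subislands": n_ok,
               "is_full_island": sub >= edge_um}
        for p in BEAT_PARAMS:
            row[p] = float(np.mean(vals[p])) if vals[p] else np.nan
        out.append(row)
    return pd.DataFrame(out)
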