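import numpy as np
import pandas as pd
import pytest

import islandcardio as ic
from islandcardio import devaxis, synth
from islandcardio.synth import (Aggregate, MovieSpec, WaveformSpec,
                                make_waveform, pulse_template, render_movie,
                                synth_expression)


def dense_measure(t, y, lo_frac, hi_frac):
    """Independent dense-grid pulse measurement oracle (crossing interpolation)."""
    peak = y.max()
    ip = int(np.argmax(y))

    def x_up(level):
        seg = y[:ip + 1]
        i = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))[0]
        return t[i] + (level - y[i]) / (y[i + 1] - y[i]) * (t[i + 1] - t[i])

    def x_down(level):
        seg = y[ip:]
        i = ip + np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))[0]
        return t[i] + (y[i] - level) / (y[i] - y[i + 1]) * (t[i + 1] - t[i])

    return {
        "amplitude": peak,
        "rise": x_up(hi_frac * peak) - x_up(lo_frac * peak),
        "apd50": x_down(0.5 * peak) - x_up(0.5 * peak),
        "apd30": x_down(0.7 * peak) - x_up(0.5 * peak),
        "apd70": x_down(0.3 * peak) - x_up(0.5 * peak),
    }


@pytest.mark.parametrize("kind,lo,hi,apd50,rise", [
    ("voltage", 0.2, 0.8, 0.30, 0.050),
    ("voltage", 0.2, 0.8, 0.45, 0.120),
    ("calcium", 0.3, 0.7, 0.40, 0.100),
])
def test_pulse_template_matches_spec(kind, lo, hi, apd50, rise):
    spec = WaveformSpec(kind=kind, period_s=1.2, amplitude=0.5,
                        apd50_s=apd50, rise_time_s=rise)
    t, y, _ = pulse_template(spec)
    m = dense_measure(t, y, lo, hi)
    assert m["amplitude"] == pytest.approx(0.5, rel=1e-6)
    assert m["apd50"] == pytest.approx(apd50, abs=0.01 * apd50)
    assert m["rise"] == pytest.approx(rise, abs=0.02 * rise)
    assert m["apd30"] < m["apd50"] < m["apd70"]


def test_waveform_zero_amplitude_is_flat():
    spec = WaveformSpec(amplitude=0.0)
    tr = make_waveform(spec, np.linspace(0, 5, 1000))
    assert not tr.any()


def test_waveform_spec_validation():
    with pytest.raises(ValueError):
        WaveformSpec(rise_time_s=0.4, apd50_s=0.3)
    with pytest.raises(ValueError):
        WaveformSpec(kind="ph")


def test_render_movie_deterministic(small_layout, voltage_spec):
    spec = MovieSpec(layout=small_layout, waveform=voltage_spec,
                     frame_rate_hz=100, duration_s=5, seed=4)
    m1, _ = render_movie(spec)
    m2, _ = render_movie(spec)
    assert np.array_equal(m1, m2)


def test_render_movie_noiseless_identity(clean_movie):
    """Without noise/bleach, the on-island mean recovers dF/F exactly."""
    movie, gt = clean_movie
    spec = gt.spec
    mask = gt.labels == 1
    isl = gt.islands.iloc[0]
    times = np.arange(movie.shape[0]) / spec.frame_rate_hz
    base = spec.waveform
    wf = WaveformSpec(kind=base.kind, period_s=isl["period"],
                      amplitude=base.amplitude, apd50_s=base.apd50_s,
                      rise_time_s=base.rise_time_s, f0=base.f0)
    expected = make_waveform(wf, times, phase_s=isl["phase"])
    recovered = (movie[:, mask].astype(np.float64).mean(axis=1)
                 - spec.background_level - isl["f0"]) / isl["f0"]
    assert np.abs(recovered - expected).max() < 1e-6


def test_render_movie_ground_truth_beat_count(clean_movie):
    movie, gt = clean_movie
    isl = gt.islands.iloc[0]
    n_expected = int((gt.spec.duration_s - isl["phase"]) // isl["period"])
    assert abs(len(gt.beats) - n_expected) <= 1


def test_render_movie_rejects_too_short_record(small_layout, voltage_spec):
    spec = MovieSpec(layout=small_layout, waveform=voltage_spec,
                     frame_rate_hz=100, duration_s=2.0, seed=1)
    with pytest.raises(ValueError):
        render_movie(spec)


def test_movie_tiff_roundtrip(tmp_path, clean_movie):
    movie, gt = clean_movie
    path = tmp_path / "mov.tif"
    synth.save_movie(path, movie, gt)
    back = synth.load_movie(path)
    assert back.shape == movie.shape
    assert np.abs(back - np.round(movie)).max() <= 1.0
    assert (tmp_path / "mov.tif.json").exists()


# ---------------------------------------------------------------------------
# expression generator

def test_expression_columns_sum_to_million():
    tpm, _ = synth_expression(n_genes=800, seed=0)
    np.testing.assert_allclose(tpm.sum(axis=0), 1e6, atol=1e-3)


def test_expression_zscore_property():
    tpm, _ = synth_expression(n_genes=500, seed=1)
    z = devaxis.zscore(devaxis.log_transform(tpm))
    assert np.abs(z.mean(axis=1)).max() < 1e-6
    np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-6)


def test_expression_noiseless_projection_identity():
    """Groups planted at 0, 0.5 and 1 project to exactly those positions."""
    # baselines high enough that no gene clips at TPM = 0 (clipping breaks
    # the log-space linearity the identity relies on)
    tpm, truth = synth_expression(
        n_genes=400, noise_sd=0.0, normalize=False, seed=2,
        baseline_mean=8.0, baseline_sd=1.0,
        samples_per_group={"CP": 3, "Adult-CM": 3, "mid": 3},
        group_positions={"CP": 0.0, "Adult-CM": 1.0, "mid": 0.5})
    logm = devaxis.log_transform(tpm)
    g = truth["groups"]
    ax = devaxis.define_axis(logm, g.index[g == "CP"], g.index[g == "Adult-CM"])
    pos = devaxis.project(logm, ax)
    np.testing.assert_allclose(pos[g == "mid"], 0.5, atol=1e-9)
    np.testing.assert_allclose(pos[g == "CP"], 0.0, atol=1e-9)


def test_expression_planted_separation_recovery():
    tpm, truth = synth_expression(n_genes=2000, seed=3)
    g = truth["groups"]
    keep = devaxis.filter_expressed(tpm, g, groups=("small", "confluent"))
    logm = devaxis.log_transform(tpm.loc[keep])
    ax = devaxis.define_axis(logm, g.index[g == "CP"], g.index[g == "Adult-CM"])
    pos = devaxis.project(logm, ax)
    d, sem, _ = devaxis.percent_closer(pos[g == "small"], pos[g == "confluent"])
    assert d == pytest.approx(4.7, abs=3 * sem)


def test_expression_position_bounds_checked():
    with pytest.raises(ValueError):
        synth_expression(n_genes=200, group_positions={"CP": 0.0, "Adult-CM": 2.0,
                                                       "small": 0.5, "confluent": 0.5})
    with pytest.raises(ValueError):
        synth_expression(n_genes=50)
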