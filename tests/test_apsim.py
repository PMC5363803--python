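import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from islandcardio import apsim
from islandcardio._bs23 import _rhs as jit_rhs
from islandcardio.apsim import (APParams, LatticeState, MeasurementError,
                                ap_rhs, beat_period, calibrate_phi,
                                conduction_velocity, fastest_cell_null,
                                intrinsic_periods, sample_leak, simulate_island,
                                size_sweep, trace_peak_times)

FAST = APParams(t_span=(0.0, 60.0))


def scipy_rk23_trace(c, params, t_eval):
    """Independent trajectory oracle: scipy's RK23 on the same lattice ODEs."""
    rows, cols = c.shape

    def rhs(t, y):
        u = y[:rows * cols].reshape(rows, cols)
        v = y[rows * cols:].reshape(rows, cols)
        du, dv = ap_rhs(LatticeState(u=u, v=v, c=c), params)
        return np.concatenate([du.ravel(), dv.ravel()])

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), np.zeros(2 * rows * cols),
                    method="RK23", rtol=params.rtol, atol=params.atol,
                    t_eval=t_eval)
    return sol.y[:rows * cols].reshape(rows, cols, -1).mean(axis=(0, 1))


def test_rhs_vanishes_at_origin():
    s = LatticeState(u=np.zeros((3, 3)), v=np.zeros((3, 3)), c=np.zeros((3, 3)))
    du, dv = ap_rhs(s, APParams())
    assert not du.any() and not dv.any()


def test_rhs_single_excited_cell():
    s = LatticeState(u=np.ones((1, 1)), v=np.zeros((1, 1)), c=np.zeros((1, 1)))
    du, dv = ap_rhs(s, APParams())
    # cubic term vanishes at u=1; recovery runs at the slow rate: 0.1*10*1
    assert du[0, 0] == pytest.approx(0.0)
    assert dv[0, 0] == pytest.approx(1.0)


def test_rhs_uniform_lattice_has_zero_coupling():
    u = np.full((2, 2), 0.37)
    v = np.full((2, 2), 0.11)
    c = np.full((2, 2), 0.09)
    coupled = ap_rhs(LatticeState(u=u, v=v, c=c), APParams(phi=400))
    uncoupled = ap_rhs(LatticeState(u=u, v=v, c=c), APParams(phi=0))
    np.testing.assert_allclose(coupled[0], uncoupled[0], rtol=0, atol=1e-14)


def test_rhs_shape_mismatch_raises():
    with pytest.raises(ValueError):
        LatticeState(u=np.zeros((2, 2)), v=np.zeros((2, 2)), c=np.zeros((3, 2)))


@pytest.mark.parametrize("boundary", ["noflux", "truncate"])
def test_jitted_rhs_matches_reference(boundary):
    rng = np.random.default_rng(0)
    u = rng.uniform(0, 1, (5, 7))
    v = rng.uniform(0, 2, (5, 7))
    c = rng.uniform(0, 0.2, (5, 7))
    p = APParams(boundary=boundary)
    du_ref, dv_ref = ap_rhs(LatticeState(u=u, v=v, c=c), p)
    du = np.empty((1, 5, 7))
    dv = np.empty((1, 5, 7))
    jit_rhs(u[None].copy(), v[None].copy(), c[None].copy(), p.k, p.a, p.phi,
            p.eps_low, p.eps_high, p.u_switch, boundary == "noflux", du, dv)
    np.testing.assert_allclose(du[0], du_ref, rtol=1e-13)
    np.testing.assert_allclose(dv[0], dv_ref, rtol=1e-13)


def test_sample_leak_statistics_and_determinism():
    assert (sample_leak(3, 3, 0.09, 0.0, seed=1) == 0.09).all()
    c1 = sample_leak(100, 100, 0.09, 0.22, seed=5)
    c2 = sample_leak(100, 100, 0.09, 0.22, seed=5)
    assert np.array_equal(c1, c2)
    se = 0.22 * 0.09 / 100
    assert abs(c1.mean() - 0.09) < 3 * se
    assert abs(c1.std() / c1.mean() - 0.22) < 0.022
    with pytest.raises(ValueError):
        sample_leak(2, 2, -0.1)


def test_single_cell_oscillates_and_matches_scipy():
    res = simulate_island(1, 1, FAST, c=np.array([[0.09]]))
    pk = trace_peak_times(res.times, res.I)
    assert pk.size >= 3
    oracle = scipy_rk23_trace(np.array([[0.09]]), FAST, res.times)
    assert np.abs(oracle - res.I).max() < 1e-2


def test_lattice_trajectory_matches_scipy():
    c = sample_leak(3, 3, seed=2)
    p = APParams(t_span=(0.0, 20.0))
    res = simulate_island(3, 3, p, c=c)
    oracle = scipy_rk23_trace(c, p, res.times)
    assert np.abs(oracle - res.I).max() < 1e-2


def test_beat_period_analytic_and_undefined():
    t = np.linspace(0, 100, 5001)
    res = apsim.SimResult(times=t, I=np.sin(2 * np.pi * t / 10), c=np.zeros((1, 1)))
    assert beat_period(res) == pytest.approx(10.0, rel=1e-3)
    res2 = apsim.SimResult(times=t, I=t * 0.01, c=np.zeros((1, 1)))
    assert np.isnan(beat_period(res2))


def test_beat_period_agrees_with_autocorrelation_oracle():
    res = simulate_island(1, 1, APParams(), c=np.array([[0.09]]))
    per = beat_period(res)
    # oracle: first peak of the autocorrelation of the (detrended) trace
    x = res.I - res.I.mean()
    acf = np.correlate(x, x, mode="full")[x.size - 1:]
    from scipy.signal import find_peaks
    idx, _ = find_peaks(acf, height=0.2 * acf[0])
    dt = res.times[1] - res.times[0]
    assert per == pytest.approx(idx[0] * dt, rel=0.02)


def test_uncoupled_cells_beat_at_distinct_rates():
    c = np.array([[0.06, 0.13]])
    p = replace(FAST, phi=0.0)
    res = simulate_island(1, 2, p, c=c, store_fields=True)
    counts = [trace_peak_times(res.times, res.u_traces[:, 0, j]).size
              for j in range(2)]
    assert counts[0] != counts[1]


def test_size_sweep_determinism_and_degenerate_cv():
    p = replace(FAST, c_cv=0.0)
    per1, s1 = size_sweep(sizes=(1, 2), n_reps=2, params=p, seed=9)
    per2, _ = size_sweep(sizes=(1, 2), n_reps=2, params=p, seed=9)
    assert np.array_equal(per1["period"], per2["period"])
    # zero heterogeneity: identical periods across reps and sizes
    assert per1["period"].std() < 1e-6
    assert s1["std"].fillna(0).max() < 1e-6


def test_fastest_cell_null_monotone_and_matches_brute_force():
    rng_draw = lambda r, n: r.lognormal(np.log(14.0), 0.12, n)
    df = fastest_cell_null(sizes=(1, 2, 4, 8), n_reps=4000,
                           period_distribution=rng_draw, seed=1)
    means = df["mean"].to_numpy()
    assert (np.diff(means) < 0).all()
    # brute-force oracle for N=4: empirical mean of min over 1e5 draws
    r = np.random.default_rng(123)
    oracle = r.lognormal(np.log(14.0), 0.12, (100000, 4)).min(axis=1).mean()
    got = float(df.loc[df["size"] == 2, "mean"].iloc[0])
    assert got == pytest.approx(oracle, rel=0.01)


def test_fastest_cell_null_degenerate_distribution():
    df = fastest_cell_null(sizes=(1, 4, 16), n_reps=100,
                           period_distribution=np.full(10, 14.0), seed=0)
    assert df["mean"].nunique() == 1


def test_conduction_requires_coupling():
    with pytest.raises(MeasurementError):
        conduction_velocity(params=replace(APParams(), phi=0.0))


def test_conduction_velocity_diffusive_scaling_and_linearity():
    m1 = conduction_velocity(params=replace(APParams(), phi=100.0))
    m4 = conduction_velocity(params=replace(APParams(), phi=400.0))
    assert m1.r_squared > 0.99 and m4.r_squared > 0.99
    ratio = m4.velocity_cells_per_time / m1.velocity_cells_per_time
    assert ratio == pytest.approx(2.0, rel=0.10)
    phys = conduction_velocity(params=APParams(), time_unit_s=0.1)
    assert phys.velocity_mm_per_s == pytest.approx(
        phys.velocity_cells_per_time * 0.0625 / 0.1)


def test_calibrate_phi_roundtrip():
    target = conduction_velocity(params=APParams()).velocity_cells_per_time
    phi, achieved = calibrate_phi(target)
    assert phi == pytest.approx(400.0, rel=0.15)
    assert achieved == pytest.approx(target, rel=0.06)
    with pytest.raises(ValueError):
        calibrate_phi(0.0)
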