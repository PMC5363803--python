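"""Adaptive Bogacki-Shampine 2(3) integrator for batched excitable lattices.

The reaction-diffusion lattice at strong coupling is stability-limited to
step sizes of order 1/(8*phi), so a sweep over many leak-matrix replicates
needs hundreds of thousands of cheap steps; this jitted loop integrates a
whole batch of lattices in one pass and emits cubic-Hermite dense output
on a fixed grid.  The pair, error estimate, and step controller follow the
classic BS23 scheme (the method behind MATLAB's ode23 and scipy's RK23).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STEP_UNDERFLOW = 1


@njit(cache=True)
def _rhs(u, v, c, k, a, phi, eps_lo, eps_hi, u_switch, noflux, du, dv):
    B, R, C = u.shape
    for b in range(B):
        for i in range(R):
            for j in range(C):
                uc = u[b, i, j]
                # neighbour sum with either mirrored (no-flux) or truncated edges
                acc = 0.0
                cnt = 0
                if i > 0:
                    acc += u[b, i - 1, j]; cnt += 1
                if i < R - 1:
                    acc += u[b, i + 1, j]; cnt += 1
                if j > 0:
                    acc += u[b, i, j - 1]; cnt += 1
                if j < C - 1:
                    acc += u[b, i, j + 1]; cnt += 1
                if noflux:
                    lap = acc - cnt * uc
                else:
                    lap = acc - 4.0 * uc
                du[b, i, j] = k * uc * (1.0 - uc) * (uc - a) - uc * v[b, i, j] \
                    + c[b, i, j] + phi * lap
                eps = eps_lo if uc <= u_switch else eps_hi
                dv[b, i, j] = eps * (k * uc - v[b, i, j])


@njit(cache=True)
def integrate_bs23(u0, v0, c, k, a, phi, eps_lo, eps_hi, u_switch, noflux,
                   t0, t1, rtol, atol, t_out, store_fields):
    """Integrate the lattice ODEs over [t0, t1], sampling at t_out.

    Returns (status, I_out, U_out, V_out, n_steps, n_rejected) where
    I_out[m, b] is the lattice-mean excitation of batch member b at
    t_out[m] and U_out/V_out hold full fields when store_fields is True.
    """
    B, R, C = u0.shape
    nout = t_out.size
    cells = R * C
    nflat = B * cells
    I_out = np.empty((nout, B))
    if store_fields:
        U_out = np.empty((nout, B, R, C))
        V_out = np.empty((nout, B, R, C))
    else:
        U_out = np.empty((1, 1, 1, 1))
        V_out = np.empty((1, 1, 1, 1))

    u = u0.copy(); v = v0.copy()
    k1u = np.empty_like(u); k1v = np.empty_like(v)
    k2u = np.empty_like(u); k2v = np.empty_like(v)
    k3u = np.empty_like(u); k3v = np.empty_like(v)
    k4u = np.empty_like(u); k4v = np.empty_like(v)
    un = np.empty_like(u); vn = np.empty_like(v)
    tu = np.empty_like(u); tv = np.empty_like(v)

    uf = u.reshape(nflat); vf = v.reshape(nflat)
    unf = un.reshape(nflat); vnf = vn.reshape(nflat)
    tuf = tu.reshape(nflat); tvf = tv.reshape(nflat)
    k1uf = k1u.reshape(nflat); k1vf = k1v.reshape(nflat)
    k2uf = k2u.reshape(nflat); k2vf = k2v.reshape(nflat)
    k3uf = k3u.reshape(nflat); k3vf = k3v.reshape(nflat)
    k4uf = k4u.reshape(nflat); k4vf = k4v.reshape(nflat)

    t = t0
    dt = min(1e-4, (t1 - t0) * 1e-6 + 1e-12)
    dt_min = 1e-13 * max(1.0, abs(t1))
    _rhs(u, v, c, k, a, phi, eps_lo, eps_hi, u_switch, noflux, k1u, k1v)

    i_out = 0
    while i_out < nout and t_out[i_out] <= t0:
        for b in range(B):
            s = 0.0
            for i in range(R):
                for j in range(C):
                    s += u[b, i, j]
            I_out[i_out, b] = s / cells
        if store_fields:
            U_out[i_out] = u
            V_out[i_out] = v
        i_out += 1

    n_steps = 0
    n_rejected = 0
    while t < t1:
        if dt < dt_min:
            return STATUS_STEP_UNDERFLOW, I_out, U_out, V_out, n_steps, n_rejected
        if t + dt > t1:
            dt = t1 - t
        # stage 2
        for m in range(nflat):
            tuf[m] = uf[m] + 0.5 * dt * k1uf[m]
            tvf[m] = vf[m] + 0.5 * dt * k1vf[m]
        _rhs(tu, tv, c, k, a, phi, eps_lo, eps_hi, u_switch, noflux, k2u, k2v)
        # stage 3
        for m in range(nflat):
            tuf[m] = uf[m] + 0.75 * dt * k2uf[m]
            tvf[m] = vf[m] + 0.75 * dt * k2vf[m]
        _rhs(tu, tv, c, k, a, phi, eps_lo, eps_hi, u_switch, noflux, k3u, k3v)
        # 3rd-order solution
        for m in range(nflat):
            unf[m] = uf[m] + dt * (2.0 / 9.0 * k1uf[m] + 1.0 / 3.0 * k2uf[m]
                                   + 4.0 / 9.0 * k3uf[m])
            vnf[m] = vf[m] + dt * (2.0 / 9.0 * k1vf[m] + 1.0 / 3.0 * k2vf[m]
                                   + 4.0 / 9.0 * k3vf[m])
        _rhs(un, vn, c, k, a, phi, eps_lo, eps_hi, u_switch, noflux, k4u, k4v)
        # embedded 2nd-order error estimate, scaled RMS norm
        s = 0.0
        for m in range(nflat):
            e = dt * (5.0 / 72.0 * k1uf[m] - 1.0 / 12.0 * k2uf[m]
                      - 1.0 / 9.0 * k3uf[m] + 1.0 / 8.0 * k4uf[m])
            sc = atol + rtol * max(abs(uf[m]), abs(unf[m]))
            e /= sc
            s += e * e
            e = dt * (5.0 / 72.0 * k1vf[m] - 1.0 / 12.0 * k2vf[m]
                      - 1.0 / 9.0 * k3vf[m] + 1.0 / 8.0 * k4vf[m])
            sc = atol + rtol * max(abs(vf[m]), abs(vnf[m]))
            e /= sc
            s += e * e
        err = np.sqrt(s / (2.0 * nflat))

        if err <= 1.0:
            t_new = t + dt
            # dense output: cubic Hermite on (u, k1) -> (un, k4)
            while i_out < nout and t_out[i_out] <= t_new + 1e-15:
                tau = (t_out[i_out] - t) / dt
                h00 = (1.0 + 2.0 * tau) * (1.0 - tau) * (1.0 - tau)
                h10 = tau * (1.0 - tau) * (1.0 - tau)
                h01 = tau * tau * (3.0 - 2.0 * tau)
                h11 = tau * tau * (tau - 1.0)
                for b in range(B):
                    s2 = 0.0
                    for i in range(R):
                        for j in range(C):
                            val = (h00 * u[b, i, j] + h10 * dt * k1u[b, i, j]
                                   + h01 * un[b, i, j] + h11 * dt * k4u[b, i, j])
                            s2 += val
                            if store_fields:
                                U_out[i_out, b, i, j] = val
                                V_out[i_out, b, i, j] = (h00 * v[b, i, j]
                                                         + h10 * dt * k1v[b, i, j]
                                                         + h01 * vn[b, i, j]
                                                         + h11 * dt * k4v[b, i, j])
                    I_out[i_out, b] = s2 / cells
                i_out += 1
            # advance; FSAL: k4 becomes next step's k1
            for m in range(nflat):
                uf[m] = unf[m]
                vf[m] = vnf[m]
                k1uf[m] = k4uf[m]
                k1vf[m] = k4vf[m]
            t = t_new
            n_steps += 1
            if err == 0.0:
                dt *= 5.0
            else:
                dt *= min(5.0, max(0.2, 0.9 * err ** (-1.0 / 3.0)))
        else:
            n_rejected += 1
            dt *= max(0.2, 0.9 * err ** (-1.0 / 3.0))
    # flush output points the final (possibly shortened) step left behind
    while i_out < nout:
        for b in range(B):
            s2 = 0.0
            for i in range(R):
                for j in range(C):
                    s2 += u[b, i, j]
                    if store_fields:
                        U_out[i_out, b, i, j] = u[b, i, j]
                        V_out[i_out, b, i, j] = v[b, i, j]
            I_out[i_out, b] = s2 / cells
        i_out += 1
    return STATUS_OK, I_out, U_out, V_out, n_steps, n_rejected
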