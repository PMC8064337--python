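"""Numba-compiled numerical kernels.

Hot loops only: ensemble relaxation of the deterministic switch (with optional
quasi-potential accumulation), the coupled multi-switch ensemble integrator,
and the Euler–Maruyama Langevin integrator with on-line dwell bookkeeping.
All kernels take plain floats/ndarrays so they stay cache-friendly under numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _f(y, z, ay, az, by, bz, bc):
    """Vector field of the resource-coupled switch at one point."""
    uy = 1.0 / (1.0 + z * z)
    uz = 1.0 / (1.0 + y * y)
    den = 1.0 + by * uy + bz * uz + bc
    fy = ay * uy / den - y
    fz = az * uz / den - z
    return fy, fz


@njit(cache=True)
def settle_ensemble(y0, z0, ay, az, by, bz, bc, dt, t_max, ftol, accumulate_v):
    """Relax every (y0[i], z0[i]) to steady state with fixed-step RK4.

    Points are frozen once the vector-field norm drops below ``ftol``.
    If ``accumulate_v`` the quasi-potential drop -dV = (fy^2 + fz^2) dt is
    accumulated along each trajectory with an RK4-consistent quadrature, so
    ``v[i]`` is the potential of the start point relative to its attractor.

    Returns (y, z, v, converged).
    """
    n = y0.shape[0]
    y = y0.copy()
    z = z0.copy()
    v = np.zeros(n)
    done = np.zeros(n, dtype=np.bool_)
    n_steps = int(t_max / dt)
    tol2 = ftol * ftol
    for _ in range(n_steps):
        all_done = True
        for i in range(n):
            if done[i]:
                continue
            yi = y[i]
            zi = z[i]
            k1y, k1z = _f(yi, zi, ay, az, by, bz, bc)
            if k1y * k1y + k1z * k1z < tol2:
                done[i] = True
                continue
            all_done = False
            h = dt
            k2y, k2z = _f(yi + 0.5 * h * k1y, zi + 0.5 * h * k1z, ay, az, by, bz, bc)
            k3y, k3z = _f(yi + 0.5 * h * k2y, zi + 0.5 * h * k2z, ay, az, by, bz, bc)
            k4y, k4z = _f(yi + h * k3y, zi + h * k3z, ay, az, by, bz, bc)
            y[i] = yi + h / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
            z[i] = zi + h / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
            if y[i] < 0.0:
                y[i] = 0.0
            if z[i] < 0.0:
                z[i] = 0.0
            if accumulate_v:
                s1 = k1y * k1y + k1z * k1z
                s2 = k2y * k2y + k2z * k2z
                s3 = k3y * k3y + k3z * k3z
                s4 = k4y * k4y + k4z * k4z
                v[i] += h / 6.0 * (s1 + 2.0 * s2 + 2.0 * s3 + s4)
        if all_done:
            break
    conv = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        fy, fz = _f(y[i], z[i], ay, az, by, bz, bc)
        conv[i] = fy * fy + fz * fz < tol2 * 100.0
    return y, z, v, conv


@njit(cache=True)
def settle_multiswitch(states0, ay, az, by, bz, dt, t_max, ftol):
    """Relax an ensemble of N coupled switches with fixed-step RK4.

    ``states0``: (n_ic, 2N) array, switch i occupying columns (2i, 2i+1);
    ``ay``..``bz``: per-switch parameter arrays of length N.  Each switch's
    denominator carries the instantaneous sequestration of all N switches
    (its own plus the context load of the other N-1).

    Returns (states, converged).
    """
    n_ic, dim = states0.shape
    nsw = dim // 2
    x = states0.copy()
    deriv = np.empty(dim)
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    tmp = np.empty(dim)
    done = np.zeros(n_ic, dtype=np.bool_)
    n_steps = int(t_max / dt)
    tol2 = ftol * ftol

    for _ in range(n_steps):
        all_done = True
        for m in range(n_ic):
            if done[m]:
                continue
            # k1 and convergence check
            _coupled_f(x[m], ay, az, by, bz, nsw, k1)
            s = 0.0
            for d in range(dim):
                s += k1[d] * k1[d]
            if s < tol2:
                done[m] = True
                continue
            all_done = False
            h = dt
            for d in range(dim):
                tmp[d] = x[m, d] + 0.5 * h * k1[d]
            _coupled_f(tmp, ay, az, by, bz, nsw, k2)
            for d in range(dim):
                tmp[d] = x[m, d] + 0.5 * h * k2[d]
            _coupled_f(tmp, ay, az, by, bz, nsw, k3)
            for d in range(dim):
                tmp[d] = x[m, d] + h * k3[d]
            _coupled_f(tmp, ay, az, by, bz, nsw, k4)
            for d in range(dim):
                x[m, d] += h / 6.0 * (k1[d] + 2.0 * k2[d] + 2.0 * k3[d] + k4[d])
                if x[m, d] < 0.0:
                    x[m, d] = 0.0
        if all_done:
            break

    conv = np.zeros(n_ic, dtype=np.bool_)
    for m in range(n_ic):
        _coupled_f(x[m], ay, az, by, bz, nsw, deriv)
        s = 0.0
        for d in range(dim):
            s += deriv[d] * deriv[d]
        conv[m] = s < tol2 * 100.0
    return x, conv


@njit(cache=True, inline="always")
def _coupled_f(x, ay, az, by, bz, nsw, out):
    """Derivative of N resource-coupled switches; writes into ``out``."""
    total = 0.0  # sum of all switches' sequestration terms
    for j in range(nsw):
        yj = x[2 * j]
        zj = x[2 * j + 1]
        total += by[j] / (1.0 + zj * zj) + bz[j] / (1.0 + yj * yj)
    for i in range(nsw):
        yi = x[2 * i]
        zi = x[2 * i + 1]
        uy = 1.0 / (1.0 + zi * zi)
        uz = 1.0 / (1.0 + yi * yi)
        den = 1.0 + total  # own terms + context of the others
        out[2 * i] = ay[i] * uy / den - yi
        out[2 * i + 1] = az[i] * uz / den - zi


@njit(cache=True)
def langevin_em(y0, z0, ay, az, by, bz, bc, eps, dt, n_steps, seed,
                fp1y, fp1z, fp2y, fp2z, radius, sample_stride, max_events):
    """Euler–Maruyama path of the Langevin switch with dwell bookkeeping.

    Additive noise of intensity ``eps`` enters both coordinates with increment
    std ``sqrt(2 eps dt)``; the state reflects at the axes (concentrations are
    nonnegative).  A basin transition is scored only on entering the disc of
    radius ``radius`` around the opposite stable fixed point (hysteresis), so
    brief separatrix crossings do not count.

    Returns (ys, zs, ts) strided samples, (event_times, event_basins) for the
    first ``max_events`` basin entries, and the number of events.  Basin code:
    0 for the (fp1y, fp1z) state, 1 for (fp2y, fp2z).
    """
    np.random.seed(seed)
    n_samples = n_steps // sample_stride + 1
    ys = np.empty(n_samples)
    zs = np.empty(n_samples)
    ts = np.empty(n_samples)
    event_times = np.empty(max_events)
    event_basins = np.empty(max_events, dtype=np.int64)
    n_events = 0

    y = y0
    z = z0
    r2 = radius * radius
    # initial basin from proximity; -1 if in neither capture disc
    basin = -1
    if (y - fp1y) ** 2 + (z - fp1z) ** 2 < r2:
        basin = 0
    elif (y - fp2y) ** 2 + (z - fp2z) ** 2 < r2:
        basin = 1
    ys[0] = y
    zs[0] = z
    ts[0] = 0.0
    k = 1
    amp = np.sqrt(2.0 * eps * dt)
    for step in range(1, n_steps + 1):
        fy, fz = _f(y, z, ay, az, by, bz, bc)
        y += fy * dt
        z += fz * dt
        if eps > 0.0:
            y += amp * np.random.normal()
            z += amp * np.random.normal()
        if y < 0.0:
            y = -y
        if z < 0.0:
            z = -z
        if basin != 0 and (y - fp1y) ** 2 + (z - fp1z) ** 2 < r2:
            basin = 0
            if n_events < max_events:
                event_times[n_events] = step * dt
                event_basins[n_events] = 0
                n_events += 1
        elif basin != 1 and (y - fp2y) ** 2 + (z - fp2z) ** 2 < r2:
            basin = 1
            if n_events < max_events:
                event_times[n_events] = step * dt
                event_basins[n_events] = 1
                n_events += 1
        if step % sample_stride == 0:
            ys[k] = y
            zs[k] = z
            ts[k] = step * dt
            k += 1
    return ys[:k], zs[:k], ts[:k], event_times[:n_events], event_basins[:n_events], n_events
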