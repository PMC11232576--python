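"""Independent reference implementations used only by the tests.

These deliberately re-derive the expected results through different
algorithms than the package: a segment-wise augmented-matrix-exponential
closed form for the linear compartment systems, a scalar closed form for the
single-fluid model, a fixed-step RK4 integrator with explicit history
interpolation for the delay model, and a brute-force grid search for the
optimizer.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def input_breakpoints(protocol):
    """(knots, levels) of the normalized input over [0, inf)."""
    breaks, levels = protocol.levels()
    return list(breaks), list(levels)


def closed_form_states(A, B, protocol, times):
    """Exact x(t) for x' = Ax + B u(t), piecewise-constant u, x(0) = 0.

    Independent route: for every requested time, propagate from 0 through
    the input segments with one augmented matrix exponential per segment.
    """
    knots, levels = input_breakpoints(protocol)
    n = A.shape[0]
    out = np.zeros((len(times), n))
    for j, t in enumerate(np.asarray(times, float)):
        x = np.zeros(n)
        for i, u in enumerate(levels + [0.0]):
            lo = knots[i] if i < len(knots) else knots[-1]
            hi = knots[i + 1] if i + 1 < len(knots) else t
            if t <= lo:
                break
            seg_end = min(hi, t)
            dt = seg_end - lo
            if dt <= 0:
                continue
            M = np.zeros((n + 1, n + 1))
            M[:n, :n] = A * dt
            M[:n, n] = B * u * dt
            E = expm(M)
            x = E[:n, :n] @ x + E[:n, n]
            if seg_end >= t:
                break
        out[j] = x
    return out


def single_fluid_scalar(a, b, k_g, protocol, times):
    """Scalar closed form of g' = k_g(u - g), r' = a g - b r.

    Derived and coded independently of the package's implementation
    (different formulation via convolution integrals per segment).
    """
    knots, levels = input_breakpoints(protocol)
    out_g, out_r = [], []
    for t in np.asarray(times, float):
        g, r = 0.0, 0.0
        segs = []
        for i, u in enumerate(levels):
            lo, hi = knots[i], knots[i + 1]
            if t > lo:
                segs.append((lo, min(hi, t), u))
        if t > knots[-1]:
            segs.append((knots[-1], t, 0.0))
        for lo, hi, u in segs:
            dt = hi - lo
            ek, eb = np.exp(-k_g * dt), np.exp(-b * dt)
            g_new = u + (g - u) * ek
            # r(t) = r e^{-b dt} + a \int_0^{dt} g(s) e^{-b(dt-s)} ds
            if b > 0:
                c1 = u / b * (1 - eb)
            else:
                c1 = u * dt
            if abs(k_g - b) > 1e-9:
                c2 = (g - u) * (ek - eb) / (b - k_g)
            else:
                c2 = (g - u) * dt * ek
            r = r * eb + a * (c1 + c2)
            g = g_new
        out_g.append(g)
        out_r.append(r)
    return np.array(out_g), np.array(out_r)


def dde_rk4(base, tau, protocol, times, dt=1.0 / 1200.0):
    """Fixed-step RK4 for the delayed 2-biological-compartment model.

    States (g, p, f); f' uses p(t - tau) linearly interpolated from the
    stored solution grid, with zero history before tau.
    """
    a, b = base.a, base.b
    k_pf, k_fp = base.k_plasma_csf, base.k_csf_plasma
    e_f = base.csf_elimination
    k_g = protocol.availability_rate
    knots, levels = input_breakpoints(protocol)

    def u_at(t):
        for i, u in enumerate(levels):
            if knots[i] <= t < knots[i + 1]:
                return u
        return 0.0

    t_end = float(np.max(times))
    n_steps = int(np.ceil(t_end / dt))
    grid = np.arange(n_steps + 1) * dt
    hist_p = np.zeros(n_steps + 1)

    def p_delayed(t):
        td = t - tau
        if td <= 0:
            return 0.0
        i = min(int(td / dt), n_steps - 1)
        frac = (td - grid[i]) / dt
        return hist_p[i] * (1 - frac) + hist_p[i + 1] * frac

    def rhs(t, y, u):
        # u is held at the step's midpoint level: with the step size an
        # exact divisor of the input breakpoints, u is constant per step
        g, p, f = y
        return np.array([
            k_g * (u - g),
            a * g - (b + k_pf) * p + k_fp * f,
            k_pf * p_delayed(t) - (k_fp + e_f) * f,
        ])

    y = np.zeros(3)
    states = np.zeros((n_steps + 1, 3))
    for i in range(n_steps):
        t = grid[i]
        u = u_at(t + dt / 2)
        k1 = rhs(t, y, u)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1, u)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2, u)
        k4 = rhs(t + dt, y + dt * k3, u)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        states[i + 1] = y
        hist_p[i + 1] = y[1]
    out = np.empty((len(times), 3))
    for j, t in enumerate(np.asarray(times, float)):
        i = min(int(t / dt), n_steps - 1)
        frac = (t - grid[i]) / dt
        out[j] = states[i] * (1 - frac) + states[i + 1] * frac
    return out


def grid_search_single(observation, protocol, a_grid, b_grid, s_grid):
    """Brute-force minimum of the weighted objective over a parameter grid."""
    ria = observation.ria
    ok = ~np.isnan(ria) & ~np.isnan(observation.i0)
    t = observation.times[ok]
    y = ria[ok]
    w = observation.i0[ok] / np.mean(observation.i0[ok])
    s_grid = np.asarray(s_grid, float)
    best = (np.inf, None)
    for a in a_grid:
        for b in b_grid:
            _, r = single_fluid_scalar(a, b, protocol.availability_rate,
                                       protocol, t)
            resid = r[None, :] - (y[None, :] - s_grid[:, None])
            sse = (w[None, :] * resid ** 2).sum(axis=1)
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (float(sse[i]), (a, b, float(s_grid[i])))
    return best
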