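"""Compiled numerical kernels (mass-action RHS/Jacobian, LNA ODEs, SSA).

All kernels operate on plain arrays extracted from a :class:`ModelSpec`:
``S`` the (species x reactions) stoichiometry, ``rates`` the per-reaction
rate constants, ``r1``/``r2`` the first/second reactant index per reaction
(-1 when absent), and ``input_idx`` the index of the zeroth-order upstream
input reaction whose rate is u(t).

Constraint: at most bimolecular reactions with distinct reactant species.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ode_rhs", "ode_jac", "lna_rhs", "ssa_run", "rk45_states", "rk45_lna"]


@njit(cache=True)
def _propensities(x, t, rates, r1, r2, input_idx, k1, k10, T, smooth):
    R = rates.shape[0]
    f = np.empty(R)
    for r in range(R):
        if r == input_idx:
            if smooth:
                f[r] = k10 + (k1 - k10) * np.exp(-t / T)
            else:
                f[r] = k1 if t < T else k10
        else:
            v = rates[r]
            if r1[r] >= 0:
                v *= x[r1[r]]
            if r2[r] >= 0:
                v *= x[r2[r]]
            f[r] = v
    return f


@njit(cache=True)
def _prop_jac(x, rates, r1, r2, input_idx):
    """d f_r / d x_s for mass-action propensities (input row is zero)."""
    R = rates.shape[0]
    n = x.shape[0]
    D = np.zeros((R, n))
    for r in range(R):
        if r == input_idx:
            continue
        i, j = r1[r], r2[r]
        if i >= 0 and j >= 0:
            D[r, i] = rates[r] * x[j]
            D[r, j] = rates[r] * x[i]
        elif i >= 0:
            D[r, i] = rates[r]
    return D


@njit(cache=True)
def ode_rhs(x, t, S, rates, r1, r2, input_idx, k1, k10, T, smooth, t0):
    f = _propensities(x, t, rates, r1, r2, input_idx, k1, k10, T, smooth)
    return S @ f


@njit(cache=True)
def ode_jac(x, t, S, rates, r1, r2, input_idx, k1, k10, T, smooth, t0):
    D = _prop_jac(x, rates, r1, r2, input_idx)
    return S @ D


@njit(cache=True)
def lna_rhs(y, t, S, rates, r1, r2, input_idx, k1, k10, T, smooth, inv_omega):
    """Joint mean + covariance ODE right-hand side.

    y[:n] is the macroscopic state, y[n:] the row-major flattened covariance.
    dSigma/dt = J Sigma + Sigma J^T + (1/Omega) S diag(f) S^T.
    """
    n = S.shape[0]
    x = y[:n]
    Sigma = y[n:].reshape((n, n))
    f = _propensities(x, t, rates, r1, r2, input_idx, k1, k10, T, smooth)
    D = _prop_jac(x, rates, r1, r2, input_idx)
    J = S @ D
    dx = S @ f
    Sf = S * f  # S @ diag(f), columnwise scaling
    diffusion = inv_omega * (Sf @ S.T)
    JS = J @ Sigma
    dSigma = JS + JS.T + diffusion
    out = np.empty(y.shape[0])
    out[:n] = dx
    out[n:] = dSigma.ravel()
    return out


@njit(cache=True)
def _ssa_segment(counts, t, t_end, Sint, rates_c, r1, r2, input_idx, u_count,
                 sample_times, out, ptr):
    """Direct-method SSA on [t, t_end) with constant input propensity.

    Records the state at every sample time passed during the segment.
    Returns (t, ptr) at segment end.
    """
    R = rates_c.shape[0]
    props = np.empty(R)
    n_samp = sample_times.shape[0]
    while True:
        a0 = 0.0
        for r in range(R):
            if r == input_idx:
                v = u_count
            else:
                v = rates_c[r]
                if r1[r] >= 0:
                    v *= counts[r1[r]]
                if r2[r] >= 0:
                    v *= counts[r2[r]]
            props[r] = v
            a0 += v
        if a0 <= 0.0:
            t_next = t_end
        else:
            t_next = t - np.log(np.random.random()) / a0
        # flush samples passed before the next jump (state is constant)
        while ptr < n_samp and sample_times[ptr] < min(t_next, t_end):
            out[ptr] = counts
            ptr += 1
        if t_next >= t_end:
            return t_end, ptr
        t = t_next
        # choose reaction
        u = np.random.random() * a0
        acc = 0.0
        rsel = R - 1
        for r in range(R):
            acc += props[r]
            if u < acc:
                rsel = r
                break
        for s in range(Sint.shape[0]):
            counts[s] += Sint[s, rsel]


@njit(cache=True)
def ssa_run(x0_counts, Sint, rates_c, r1, r2, input_idx, u1_count, u2_count,
            T_pulse, sample_times, seed):
    """Exact SSA path with piecewise-constant input; samples at given times.

    The pulse end T_pulse is treated as a hard event boundary: the segment
    propensity bookkeeping restarts there with the background input rate.
    """
    np.random.seed(seed)
    n = x0_counts.shape[0]
    n_samp = sample_times.shape[0]
    out = np.zeros((n_samp, n), dtype=np.int64)
    counts = x0_counts.copy()
    t_end = sample_times[n_samp - 1]
    ptr = 0
    if sample_times[0] <= 0.0:
        out[0] = counts
        ptr = 1
    t = 0.0
    if T_pulse < t_end:
        t, ptr = _ssa_segment(counts, t, T_pulse, Sint, rates_c, r1, r2,
                              input_idx, u1_count, sample_times, out, ptr)
        t, ptr = _ssa_segment(counts, t, t_end, Sint, rates_c, r1, r2,
                              input_idx, u2_count, sample_times, out, ptr)
    else:
        t, ptr = _ssa_segment(counts, t, t_end, Sint, rates_c, r1, r2,
                              input_idx, u1_count, sample_times, out, ptr)
    # the final sample time coincides with t_end; record it
    while ptr < n_samp:
        out[ptr] = counts
        ptr += 1
    return out


# ---------------------------------------------------------------------------
# Embedded Dormand-Prince RK45 fast path (the network is only mildly stiff
# at physiological rates; LSODA remains the fallback for hard cases)
# ---------------------------------------------------------------------------

_DP_C = np.array([0.0, 1/5, 3/10, 4/5, 8/9, 1.0, 1.0])
_DP_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1/5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3/40, 9/40, 0.0, 0.0, 0.0, 0.0],
    [44/45, -56/15, 32/9, 0.0, 0.0, 0.0],
    [19372/6561, -25360/2187, 64448/6561, -212/729, 0.0, 0.0],
    [9017/3168, -355/33, 46732/5247, 49/176, -5103/18656, 0.0],
    [35/384, 0.0, 500/1113, 125/192, -2187/6784, 11/84],
])
_DP_B5 = np.array([35/384, 0.0, 500/1113, 125/192, -2187/6784, 11/84, 0.0])
_DP_B4 = np.array([5179/57600, 0.0, 7571/16695, 393/640, -92097/339200, 187/2100, 1/40])


@njit(cache=True)
def _any_rhs(sys_kind, y, t, S, rates, r1, r2, input_idx, u, inv_omega):
    """sys_kind 0: macroscopic ODE; 1: joint LNA mean+covariance system.

    The input propensity is the constant u (segments are cut at the pulse
    boundary by the drivers below)."""
    if sys_kind == 0:
        f = _propensities(y, t, rates, r1, r2, input_idx, u, u, np.inf, False)
        return S @ f
    n = S.shape[0]
    x = y[:n]
    Sigma = np.ascontiguousarray(y[n:]).reshape((n, n))
    f = _propensities(x, t, rates, r1, r2, input_idx, u, u, np.inf, False)
    D = _prop_jac(x, rates, r1, r2, input_idx)
    J = S @ D
    Sf = S * f
    JS = J @ Sigma
    dSigma = JS + JS.T + inv_omega * (Sf @ S.T)
    out = np.empty(y.shape[0])
    out[:n] = S @ f
    out[n:] = dSigma.ravel()
    return out


@njit(cache=True)
def _dp45_segment(sys_kind, y, t0, t1, out_times, out, ptr,
                  S, rates, r1, r2, input_idx, u, inv_omega,
                  rtol, atol, max_steps):
    """Integrate one constant-input segment, writing states at out_times.

    Dense output uses a cheap cubic Hermite interpolant between accepted
    steps (adequate at the tolerances used here).  Returns (ok, t, h, ptr).
    """
    dim = y.shape[0]
    y = y.copy()
    K = np.empty((7, dim))
    h = (t1 - t0) * 0.01
    if h <= 0.0:
        return True, y, ptr
    t = t0
    f0 = _any_rhs(sys_kind, y, t, S, rates, r1, r2, input_idx, u, inv_omega)
    n_out = out_times.shape[0]
    steps = 0
    while t < t1:
        if steps > max_steps:
            return False, y, ptr
        steps += 1
        # step exactly onto the next requested output time (no dense output)
        t_cap = t1
        if ptr < n_out and out_times[ptr] < t1:
            t_cap = out_times[ptr]
        if t + h > t_cap:
            h = t_cap - t
        K[0] = f0
        for s in range(1, 7):
            acc = np.zeros(dim)
            for j in range(s):
                a = _DP_A[s, j] if s < 6 else _DP_B5[j]
                if a != 0.0:
                    acc += a * K[j]
            K[s] = _any_rhs(sys_kind, y + h * acc, t + _DP_C[s] * h,
                            S, rates, r1, r2, input_idx, u, inv_omega)
        y5 = y + h * (_DP_B5[0] * K[0] + _DP_B5[2] * K[2] + _DP_B5[3] * K[3]
                      + _DP_B5[4] * K[4] + _DP_B5[5] * K[5])
        err = 0.0
        for i in range(dim):
            e = h * ((_DP_B5[0] - _DP_B4[0]) * K[0, i]
                     + (_DP_B5[2] - _DP_B4[2]) * K[2, i]
                     + (_DP_B5[3] - _DP_B4[3]) * K[3, i]
                     + (_DP_B5[4] - _DP_B4[4]) * K[4, i]
                     + (_DP_B5[5] - _DP_B4[5]) * K[5, i]
                     - _DP_B4[6] * K[6, i])
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            err += (e / sc) ** 2
        err = np.sqrt(err / dim)
        if not np.isfinite(err):
            return False, y, ptr
        if err <= 1.0:
            h_used = h
            t_new = t + h
            y = y5
            f0 = K[6]  # FSAL: stage 7 is the RHS at (t+h, y5)
            t = t_new
            while ptr < n_out and out_times[ptr] <= t + 1e-12:
                out[ptr] = y
                ptr += 1
            fac = 0.9 * err ** -0.2 if err > 1e-10 else 5.0
            h = h_used * min(5.0, max(0.2, fac))
        else:
            h *= max(0.2, 0.9 * err ** -0.2)
        if h < 1e-12 * (t1 - t0):
            return False, y, ptr
    return True, y, ptr


@njit(cache=True)
def _rk45_drive(sys_kind, y0, times, S, rates, r1, r2, input_idx,
                k1, k10, T_pulse, inv_omega, rtol, atol, max_steps):
    dim = y0.shape[0]
    n_out = times.shape[0]
    out = np.empty((n_out, dim))
    ptr = 0
    if times[0] <= 0.0:
        out[0] = y0
        ptr = 1
    t_end = times[n_out - 1]
    if T_pulse < t_end:
        ok, y, ptr = _dp45_segment(sys_kind, y0, 0.0, T_pulse, times, out, ptr,
                                   S, rates, r1, r2, input_idx, k1, inv_omega,
                                   rtol, atol, max_steps)
        if not ok:
            return False, out
        ok, y, ptr = _dp45_segment(sys_kind, y, T_pulse, t_end, times, out, ptr,
                                   S, rates, r1, r2, input_idx, k10, inv_omega,
                                   rtol, atol, max_steps)
        if not ok:
            return False, out
    else:
        ok, y, ptr = _dp45_segment(sys_kind, y0, 0.0, t_end, times, out, ptr,
                                   S, rates, r1, r2, input_idx, k1, inv_omega,
                                   rtol, atol, max_steps)
        if not ok:
            return False, out
    while ptr < n_out:  # trailing outputs exactly at t_end
        out[ptr] = y
        ptr += 1
    return True, out


def rk45_states(y0, times, S, rates, r1, r2, input_idx, k1, k10, T_pulse,
                rtol, atol, max_steps=200_000):
    """Macroscopic states on the output grid via the compiled RK45 driver."""
    return _rk45_drive(0, y0, times, S, rates, r1, r2, input_idx,
                       k1, k10, T_pulse, 0.0, rtol, atol, max_steps)


def rk45_lna(y0, times, S, rates, r1, r2, input_idx, k1, k10, T_pulse,
             inv_omega, rtol, atol, max_steps=200_000):
    """Joint LNA mean/covariance states on the output grid."""
    return _rk45_drive(1, y0, times, S, rates, r1, r2, input_idx,
                       k1, k10, T_pulse, inv_omega, rtol, atol, max_steps)
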