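"""Numba-compiled numerical kernels.

These are the hot loops of the package: fixed-step RK4 integration of the
predator-prey system (optionally with forward sensitivities for gradient
calibration) and the day-by-day recursion of the flux mini-model.  They are
plain-number fast paths; the differentiable reference implementations live in
:mod:`pinneco.lv` and :mod:`pinneco.flux` and are tested to agree with these
kernels.

All kernels are batched over a leading axis so that many parameter vectors
(cross-validation folds x seeds, MCMC chains, Latin-hypercube draws,
ICE grid points) integrate in one call.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NU_E = 0.6  # fixed exponent of vapour-pressure deficit in the transpiration law


@njit(cache=True)
def _lv_rhs(x, y, r, b, m, s, type3):
    if type3:
        u = x * x
        den = 1.0 + s * u
        g = b * u * y / den
    else:
        g = b * x * y
    return r * x - g, g - m * y


@njit(cache=True)
def lv_rk4(params, x0, y0, type3, n_out, dt_out, substeps):
    """Batched RK4 integration of the Lotka-Volterra system.

    params: (B, 4) rows (r, b, m, s); type3: (B,) booleans; returns
    trajectories (B, n_out, 2) on the uniform output grid with spacing
    ``dt_out``, integrated internally at ``dt_out / substeps``.
    """
    B = params.shape[0]
    traj = np.empty((B, n_out, 2))
    h = dt_out / substeps
    for i in range(B):
        r, b, m, s = params[i, 0], params[i, 1], params[i, 2], params[i, 3]
        t3 = type3[i]
        x = x0[i]
        y = y0[i]
        traj[i, 0, 0] = x
        traj[i, 0, 1] = y
        for k in range(1, n_out):
            for _ in range(substeps):
                k1x, k1y = _lv_rhs(x, y, r, b, m, s, t3)
                k2x, k2y = _lv_rhs(x + 0.5 * h * k1x, y + 0.5 * h * k1y, r, b, m, s, t3)
                k3x, k3y = _lv_rhs(x + 0.5 * h * k2x, y + 0.5 * h * k2y, r, b, m, s, t3)
                k4x, k4y = _lv_rhs(x + h * k3x, y + h * k3y, r, b, m, s, t3)
                x = x + h / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
                y = y + h / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
            traj[i, k, 0] = x
            traj[i, k, 1] = y
    return traj


@njit(cache=True)
def _lv_aug_rhs(z, dz, r, b, m, s, type3):
    """RHS of the state + forward-sensitivity system.

    z layout: [x, y, Sx_r, Sx_b, Sx_m, Sx_s, Sy_r, Sy_b, Sy_m, Sy_s] where
    Sx_p = d x / d p along the trajectory.
    """
    x = z[0]
    y = z[1]
    if type3:
        u = x * x
        den = 1.0 + s * u
        g = b * u * y / den
        gx = 2.0 * b * x * y / (den * den)
        gy = b * u / den
        gb = u * y / den
        gs = -g * u / den
    else:
        g = b * x * y
        gx = b * y
        gy = b * x
        gb = x * y
        gs = 0.0
    dz[0] = r * x - g
    dz[1] = g - m * y
    jxx = r - gx
    jxy = -gy
    jyx = gx
    jyy = gy - m
    # parameter order: r, b, m, s
    dz[2] = jxx * z[2] + jxy * z[6] + x
    dz[3] = jxx * z[3] + jxy * z[7] - gb
    dz[4] = jxx * z[4] + jxy * z[8]
    dz[5] = jxx * z[5] + jxy * z[9] - gs
    dz[6] = jyx * z[2] + jyy * z[6]
    dz[7] = jyx * z[3] + jyy * z[7] + gb
    dz[8] = jyx * z[4] + jyy * z[8] - y
    dz[9] = jyx * z[5] + jyy * z[9] + gs


@njit(cache=True)
def lv_rk4_sens(params, x0, y0, type3, n_out, dt_out, substeps):
    """Batched RK4 with forward sensitivities w.r.t. (r, b, m, s).

    Returns (traj (B, n_out, 2), sens (B, n_out, 2, 4)) where
    sens[i, k, 0, p] = d x(t_k) / d p for system i.
    """
    B = params.shape[0]
    traj = np.empty((B, n_out, 2))
    sens = np.empty((B, n_out, 2, 4))
    h = dt_out / substeps
    z = np.empty(10)
    k1 = np.empty(10)
    k2 = np.empty(10)
    k3 = np.empty(10)
    k4 = np.empty(10)
    tmp = np.empty(10)
    for i in range(B):
        r, b, m, s = params[i, 0], params[i, 1], params[i, 2], params[i, 3]
        t3 = type3[i]
        for j in range(10):
            z[j] = 0.0
        z[0] = x0[i]
        z[1] = y0[i]
        traj[i, 0, 0] = z[0]
        traj[i, 0, 1] = z[1]
        for p in range(4):
            sens[i, 0, 0, p] = 0.0
            sens[i, 0, 1, p] = 0.0
        for k in range(1, n_out):
            for _ in range(substeps):
                _lv_aug_rhs(z, k1, r, b, m, s, t3)
                for j in range(10):
                    tmp[j] = z[j] + 0.5 * h * k1[j]
                _lv_aug_rhs(tmp, k2, r, b, m, s, t3)
                for j in range(10):
                    tmp[j] = z[j] + 0.5 * h * k2[j]
                _lv_aug_rhs(tmp, k3, r, b, m, s, t3)
                for j in range(10):
                    tmp[j] = z[j] + h * k3[j]
                _lv_aug_rhs(tmp, k4, r, b, m, s, t3)
                for j in range(10):
                    z[j] = z[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            traj[i, k, 0] = z[0]
            traj[i, k, 1] = z[1]
            for p in range(4):
                sens[i, k, 0, p] = z[2 + p]
                sens[i, k, 1, p] = z[6 + p]
    return traj, sens


@njit(cache=True)
def lv_rk4_sens_obs(params, x0, y0, type3, n_out, dt_out, substeps, obs_idx):
    """Like :func:`lv_rk4_sens` but returns prey predictions and prey
    sensitivities only at per-system observation grid positions
    ``obs_idx`` (B, K) -- the training hot loop of gradient calibration.
    """
    B = params.shape[0]
    K = obs_idx.shape[1]
    pred = np.empty((B, K))
    sens_obs = np.zeros((B, K, 4))
    z = np.empty(10)
    k1 = np.empty(10)
    k2 = np.empty(10)
    k3 = np.empty(10)
    k4 = np.empty(10)
    tmp = np.empty(10)
    mark = np.empty(n_out, dtype=np.int64)
    h = dt_out / substeps
    for i in range(B):
        r, b, m, s = params[i, 0], params[i, 1], params[i, 2], params[i, 3]
        t3 = type3[i]
        for k in range(n_out):
            mark[k] = -1
        for j in range(K):
            mark[obs_idx[i, j]] = j
        for j in range(10):
            z[j] = 0.0
        z[0] = x0[i]
        z[1] = y0[i]
        if mark[0] >= 0:
            pred[i, mark[0]] = z[0]
        for k in range(1, n_out):
            for _ in range(substeps):
                _lv_aug_rhs(z, k1, r, b, m, s, t3)
                for j in range(10):
                    tmp[j] = z[j] + 0.5 * h * k1[j]
                _lv_aug_rhs(tmp, k2, r, b, m, s, t3)
                for j in range(10):
                    tmp[j] = z[j] + 0.5 * h * k2[j]
                _lv_aug_rhs(tmp, k3, r, b, m, s, t3)
                for j in range(10):
                    tmp[j] = z[j] + h * k3[j]
                _lv_aug_rhs(tmp, k4, r, b, m, s, t3)
                for j in range(10):
                    z[j] = z[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if mark[k] >= 0:
                jj = mark[k]
                pred[i, jj] = z[0]
                for p in range(4):
                    sens_obs[i, jj, p] = z[2 + p]
    return pred, sens_obs


@njit(cache=True)
def flux_forward(params, covs, init_soil, init_snow):
    """Batched day-by-day recursion of the flux mini-model.

    params: (B, 11) rows (beta, t_opt, k_temp, tau_temp, kappa_vpd, wp_lo,
    wp_hi, we_hi, capacity, melt_rate, alpha_et); covs: (B, n, 6) columns
    (T, D, phi, R, fappfd, co2).  Returns (P, E, soil, snow, runoff), each
    (B, n).  Modifiers use the previous day's soil pool; rain and melt
    infiltrate the same day; soil above capacity runs off the same day.
    """
    B = params.shape[0]
    n = covs.shape[1]
    P = np.empty((B, n))
    E = np.empty((B, n))
    soil_out = np.empty((B, n))
    snow_out = np.empty((B, n))
    runoff_out = np.empty((B, n))
    for i in range(B):
        beta = params[i, 0]
        t_opt = params[i, 1]
        k_temp = params[i, 2]
        tau_temp = params[i, 3]
        kappa = params[i, 4]
        wp_lo = params[i, 5]
        wp_hi = params[i, 6]
        we_hi = params[i, 7]
        cap = params[i, 8]
        melt_rate = params[i, 9]
        alpha = params[i, 10]
        soil = init_soil[i]
        snow = init_snow[i]
        ts = covs[i, 0, 0]
        for k in range(n):
            T = covs[i, k, 0]
            D = covs[i, k, 1]
            phi = covs[i, k, 2]
            R = covs[i, k, 3]
            fappfd = covs[i, k, 4]
            if k > 0:
                ts = ts + (T - ts) / tau_temp
            f_temp = 1.0 / (1.0 + np.exp(-k_temp * (ts - t_opt)))
            f_vpd = np.exp(-kappa * D)
            w = soil / cap
            f_wp = (w - wp_lo) / (wp_hi - wp_lo)
            if f_wp < 0.0:
                f_wp = 0.0
            elif f_wp > 1.0:
                f_wp = 1.0
            f_we = w / we_hi
            if f_we < 0.0:
                f_we = 0.0
            elif f_we > 1.0:
                f_we = 1.0
            gpp = beta * phi * fappfd * f_temp * f_vpd * f_wp
            e_demand = alpha * gpp * D**NU_E * f_we
            if T <= 0.0:
                snow_in = R
                rain = 0.0
            else:
                snow_in = 0.0
                rain = R
            melt_k = melt_rate * T
            if melt_k < 0.0:
                melt_k = 0.0
            if melt_k > snow:
                melt_k = snow
            snow = snow + snow_in - melt_k
            inflow = rain + melt_k
            et = e_demand
            if et > soil + inflow:
                et = soil + inflow
            soil_t = soil + inflow - et
            runoff = soil_t - cap
            if runoff < 0.0:
                runoff = 0.0
            soil = soil_t - runoff
            P[i, k] = gpp
            E[i, k] = et
            soil_out[i, k] = soil
            snow_out[i, k] = snow
            runoff_out[i, k] = runoff
    return P, E, soil_out, snow_out, runoff_out
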