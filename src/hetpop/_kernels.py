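"""Numba-compiled inner loops.

These kernels are private: the public API lives in ``single_cell`` and
``cnmc``.  Each kernel seeds numba's own RNG stream, so a given (seed,
arguments) pair is bitwise reproducible.

``cnmc_step_kernel`` fuses the constant-number Monte Carlo cycle
(Langevin content propagation, division-time hazard accumulation,
divider selection, binary partitioning, constant-N replacement) into one
loop; the op-level reference implementations in ``cnmc`` realize the same
mechanics step by step.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _drift(x, pi, rho, kappa, invK):
    d = rho + x * x
    a = (pi * rho + x * x) / d - kappa * x
    if invK > 0.0:
        a -= (
            invK
            * 2.0
            * rho
            * x
            * (pi - 1.0)
            * (((pi - 2.0) + kappa * x) * x * x + rho * (kappa * x - pi))
            / (d * d * d * d)
        )
    return a


@njit(cache=True, inline="always")
def _diffusion(x, pi, rho, kappa, invK, invy):
    d = rho + x * x
    b = invy * (rho * (pi + kappa * x) + x * x * (1.0 + kappa * x)) / d
    if invK > 0.0:
        b += invK * rho * x * x * (pi - 1.0) * (pi - 1.0) / (d * d * d)
    if b < 0.0:
        b = 0.0
    return b


@njit(cache=True)
def langevin_paths(x0s, report_times, dt, pi, rho, kappa, invK, invy, seed):
    """Euler-Maruyama (Ito) paths with reflection at x = 0.

    Returns values[report_time, path]; report_times[0] is the initial time.
    """
    np.random.seed(seed)
    n_paths = x0s.shape[0]
    n_rep = report_times.shape[0]
    out = np.empty((n_rep, n_paths))
    for p in range(n_paths):
        x = x0s[p]
        tau = 0.0
        for ir in range(0, n_rep):
            t_next = report_times[ir]
            while tau < t_next - 1e-12:
                h = dt
                if tau + h > t_next:
                    h = t_next - tau
                b = _diffusion(x, pi, rho, kappa, invK, invy)
                x = (
                    x
                    + _drift(x, pi, rho, kappa, invK) * h
                    + np.sqrt(b * h) * np.random.standard_normal()
                )
                if x < 0.0:
                    x = -x
                tau += h
            out[ir, p] = x
    return out


@njit(cache=True, inline="always")
def _powm(t, m):
    # fast path for the common integer sharpness exponents
    if m == 2.0:
        return t * t
    if m == 3.0:
        return t * t * t
    if m == 1.0:
        return t
    if m == 0.0:
        return 1.0
    return t**m


@njit(cache=True, fastmath=True)
def cnmc_step_kernel(
    x0, tau0, report_times, dt, pi, rho, kappa, invK, invy, m, f, seed
):
    """One constant-number Monte Carlo copy.

    Contents evolve by the Langevin SDE between divisions; the division
    hazard sum_i (x_i/<x>)^m is accumulated trapezoidally along the SDE
    steps and divisions fire when it reaches Exp(1) thresholds, with the
    crossing times resolved inside the step by interpolation.  The divider
    is drawn proportionally to its hazard at the (content-interpolated)
    division time, its content is split f/(1-f) with a fair coin, the
    mother slot receives one daughter and a uniformly chosen *other* slot
    the second.

    One Euler-Maruyama proposal is drawn per step window; divisions within
    the window modify only the divided slots (daughters are held to the end
    of the window, a first-order-consistent treatment) and the population
    hazard is updated incrementally through the running moments
    S1 = sum x_i and Sm = sum x_i^m, so a division costs O(N) for divider
    selection only.

    Returns (snapshots[report, cell], n_divisions).
    """
    np.random.seed(seed)
    N = x0.shape[0]
    n_rep = report_times.shape[0]
    snaps = np.empty((n_rep, N))
    x = x0.copy()
    xn = np.empty(N)

    tau = tau0
    s1 = 0.0
    sm = 0.0
    for i in range(N):
        s1 += x[i]
        sm += _powm(x[i], m)
    gsum = sm / _powm(s1 / N, m) if s1 > 0.0 else 0.0
    hazard = 0.0
    target = -np.log(1.0 - np.random.random())
    n_div = 0
    ir = 0

    while ir < n_rep:
        if tau >= report_times[ir] - 1e-12:
            for i in range(N):
                snaps[ir, i] = x[i]
            ir += 1
            continue
        h = dt
        if tau + h > report_times[ir]:
            h = report_times[ir] - tau
        sqh = np.sqrt(h)
        # propose a full Euler-Maruyama step for every cell
        s1_n = 0.0
        sm_n = 0.0
        for i in range(N):
            b = _diffusion(x[i], pi, rho, kappa, invK, invy)
            v = (
                x[i]
                + _drift(x[i], pi, rho, kappa, invK) * h
                + np.sqrt(b) * sqh * np.random.standard_normal()
            )
            if v < 0.0:
                v = -v
            xn[i] = v
            s1_n += v
            sm_n += _powm(v, m)
        g0 = gsum
        g1 = sm_n / _powm(s1_n / N, m) if s1_n > 0.0 else 0.0
        # walk the piecewise-linear hazard g(s) = g0 + (g1 - g0) s across
        # the window, firing divisions at every threshold crossing
        s_loc = 0.0
        while True:
            rem = 0.5 * ((g0 + (g1 - g0) * s_loc) + g1) * (1.0 - s_loc) * h
            if rem <= 0.0 or hazard + rem < target:
                hazard += rem
                break
            need = target - hazard
            ga = g0 + (g1 - g0) * s_loc
            slope = (g1 - g0) * h
            # solve (slope/2) u^2 + ga h u = need for u = s - s_loc
            if np.abs(slope) > 1e-14 * (np.abs(ga) * h + 1e-300):
                disc = (ga * h) * (ga * h) + 2.0 * slope * need
                if disc < 0.0:
                    disc = 0.0
                u = (-ga * h + np.sqrt(disc)) / slope
            else:
                u = need / (ga * h) if ga > 0.0 else (1.0 - s_loc)
            s_div = s_loc + u
            if s_div > 1.0:
                s_div = 1.0
            # divider selection on the content-interpolated population
            wsum = 0.0
            for i in range(N):
                wsum += _powm(x[i] + s_div * (xn[i] - x[i]), m)
            if wsum <= 0.0:
                hazard = 0.0
                target = -np.log(1.0 - np.random.random())
                s_loc = s_div
                continue
            uu = np.random.random() * wsum
            acc = 0.0
            k = N - 1
            for i in range(N):
                acc += _powm(x[i] + s_div * (xn[i] - x[i]), m)
                if acc >= uu:
                    k = i
                    break
            xm = x[k] + s_div * (xn[k] - x[k])
            # exact-sum daughter pair (see cnmc.apply_division)
            d_big = xm - f * xm
            d_small = xm - d_big
            if np.random.random() < 0.5:
                d1 = d_small
                d2 = d_big
            else:
                d1 = d_big
                d2 = d_small
            j = np.random.randint(0, N - 1)
            if j >= k:
                j += 1
            # daughters replace the two slots and are held to window end
            s1_n += d1 + d2 - xn[k] - xn[j]
            sm_n += (
                _powm(d1, m) + _powm(d2, m) - _powm(xn[k], m)
                - _powm(xn[j], m)
            )
            x[k] = d1
            xn[k] = d1
            x[j] = d2
            xn[j] = d2
            n_div += 1
            g1 = sm_n / _powm(s1_n / N, m) if s1_n > 0.0 else 0.0
            hazard = 0.0
            target = -np.log(1.0 - np.random.random())
            s_loc = s_div
            if s_loc >= 1.0:
                break
        tmp = x
        x = xn
        xn = tmp
        s1 = s1_n
        sm = sm_n
        gsum = g1
        tau += h
    return snaps, n_div


@njit(cache=True)
def ssa_kernel(
    counts0, report_times, iex, F, n_O,
    k_r, k_mr, k_r2, k_mr2, k_t, k_Y, k_p, k_mp, k_ft, lam_Y, lam_I,
    seed,
):
    """Direct-method SSA for the elementary lac operon reactions.

    State: (Y, YIex, I, Rf, I2R, O1); O0 = n_O - O1.  Bimolecular
    concentration-based rate constants are converted with the
    molecules-per-nM factor F.  Extracellular IPTG is a fixed reservoir.
    """
    np.random.seed(seed)
    n_rep = report_times.shape[0]
    snaps = np.empty((n_rep, 6), dtype=np.int64)
    nY = counts0[0]
    nYI = counts0[1]
    nI = counts0[2]
    nRf = counts0[3]
    nI2R = counts0[4]
    nO1 = counts0[5]
    tau = 0.0
    ir = 0
    a = np.empty(12)
    while ir < n_rep:
        nO0 = n_O - nO1
        a[0] = k_r * nO0 * nRf / F          # O0 + R -> O1
        a[1] = k_mr * nO1                   # O1 -> O0 + R
        a[2] = k_r2 * nI * (nI - 1) * nRf / (F * F)  # 2I + R -> I2R
        a[3] = k_mr2 * nI2R                 # I2R -> 2I + R
        a[4] = k_t * iex * F                # reservoir -> I
        a[5] = k_t * nI                     # I -> reservoir
        a[6] = k_Y * nO0                    # O0 -> O0 + Y (transcription)
        a[7] = k_p * iex * nY               # Y + Iex -> YIex
        a[8] = k_mp * nYI                   # YIex -> Y + Iex
        a[9] = k_ft * nYI                   # YIex -> Y + I
        a[10] = lam_Y * nY                  # Y -> 0
        a[11] = lam_I * nI                  # I -> 0
        atot = 0.0
        for r in range(12):
            atot += a[r]
        if atot <= 0.0:
            tau = report_times[n_rep - 1] + 1.0
        else:
            tau += -np.log(1.0 - np.random.random()) / atot
        while ir < n_rep and tau > report_times[ir]:
            snaps[ir, 0] = nY
            snaps[ir, 1] = nYI
            snaps[ir, 2] = nI
            snaps[ir, 3] = nRf
            snaps[ir, 4] = nI2R
            snaps[ir, 5] = nO1
            ir += 1
        if ir >= n_rep:
            break
        u = np.random.random() * atot
        acc = 0.0
        r_sel = 11
        for r in range(12):
            acc += a[r]
            if acc >= u:
                r_sel = r
                break
        if r_sel == 0:
            nO1 += 1
            nRf -= 1
        elif r_sel == 1:
            nO1 -= 1
            nRf += 1
        elif r_sel == 2:
            nI -= 2
            nRf -= 1
            nI2R += 1
        elif r_sel == 3:
            nI += 2
            nRf += 1
            nI2R -= 1
        elif r_sel == 4:
            nI += 1
        elif r_sel == 5:
            nI -= 1
        elif r_sel == 6:
            nY += 1
        elif r_sel == 7:
            nY -= 1
            nYI += 1
        elif r_sel == 8:
            nY += 1
            nYI -= 1
        elif r_sel == 9:
            nY += 1
            nYI -= 1
            nI += 1
        elif r_sel == 10:
            nY -= 1
        else:
            nI -= 1
    return snaps
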