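"""Jitted inner loop for the coupled dynamics + plasticity integration.

The pure-numpy single step in :mod:`heterochunk.dynamics` is the reference
implementation of the update; this module repeats the same arithmetic in a
numba kernel so that training batteries (hundreds of epochs at dt = 0.02)
run in seconds.  A consistency test pins the two against each other.

All scalar constants travel in one float64 vector ``pv`` (see the ``I_*``
index constants); learning switches travel in a bitmask.
"""

import numpy as np
from numba import njit

# -- pv layout ---------------------------------------------------------------
(
    I_TAU_X, I_TAU_Y, I_TAU_Z, I_B_X, I_B_Y,
    I_SIG_X, I_SIG_Y, I_DT, I_FLOOR,
    I_TAU_P,
    I_TAU_V, I_ALPHA_V, I_V_LO, I_V_MID, I_V_HI, I_TH_P, I_TH_D,
    I_TAU_W, I_ALPHA_W, I_W_LO, I_W_MID, I_W_HI, I_TH_P_W, I_TH_D_W,
    I_TAU_A, I_A_PLUS, I_A_MINUS, I_TAU_A_Y,
    I_TAU_Q, I_ALPHA_Q, I_Q_LO, I_Q_MID, I_Q_HI,
    I_GP_Q, I_GD_Q, I_TH_P_Q, I_TH_D_Q, I_EPS_H, I_M_H,
    I_TAU_R, I_ALPHA_R, I_R_LO, I_R_MID, I_R_HI,
    I_GP_R, I_GD_R, I_TH_P_R, I_TH_D_R,
) = range(48)

NPV = 48

F_LEARN_P, F_LEARN_V, F_LEARN_W, F_LEARN_Q, F_LEARN_R = 1, 2, 4, 8, 16


def pack_params(model, plast):
    """Flatten ModelParams + PlasticityParams into the kernel vector."""
    pv = np.zeros(NPV)
    pv[I_TAU_X] = model.tau_x
    pv[I_TAU_Y] = model.tau_y
    pv[I_TAU_Z] = model.tau_z
    pv[I_B_X] = model.b_x
    pv[I_B_Y] = model.b_y
    pv[I_SIG_X] = model.sigma_x
    pv[I_SIG_Y] = model.sigma_y
    pv[I_DT] = model.dt
    pv[I_FLOOR] = model.floor
    pv[I_TAU_P] = plast.tau_P
    pv[I_TAU_V] = plast.tau_V
    pv[I_ALPHA_V] = plast.alpha_V
    pv[I_V_LO] = plast.V_low
    pv[I_V_MID] = plast.V_mid
    pv[I_V_HI] = plast.V_high
    pv[I_TH_P] = plast.theta_p
    pv[I_TH_D] = plast.theta_d
    pv[I_TAU_W] = plast.tau_W
    pv[I_ALPHA_W] = plast.alpha_W
    pv[I_W_LO] = plast.W_low
    pv[I_W_MID] = plast.W_mid
    pv[I_W_HI] = plast.W_high
    pv[I_TH_P_W] = plast.theta_p_W
    pv[I_TH_D_W] = plast.theta_d_W
    pv[I_TAU_A] = plast.tau_A
    pv[I_A_PLUS] = plast.A_plus
    pv[I_A_MINUS] = plast.A_minus
    pv[I_TAU_A_Y] = plast.tau_A_y
    pv[I_TAU_Q] = plast.tau_Q
    pv[I_ALPHA_Q] = plast.alpha_Q
    pv[I_Q_LO] = plast.Q_low
    pv[I_Q_MID] = plast.Q_mid
    pv[I_Q_HI] = plast.Q_high
    pv[I_GP_Q] = plast.gamma_p_Q
    pv[I_GD_Q] = plast.gamma_d_Q
    pv[I_TH_P_Q] = plast.theta_p_Q
    pv[I_TH_D_Q] = plast.theta_d_Q
    pv[I_EPS_H] = plast.eps_H
    pv[I_M_H] = plast.m_H
    pv[I_TAU_R] = plast.tau_R
    pv[I_ALPHA_R] = plast.alpha_R
    pv[I_R_LO] = plast.R_low
    pv[I_R_MID] = plast.R_mid
    pv[I_R_HI] = plast.R_high
    pv[I_GP_R] = plast.gamma_p_R
    pv[I_GD_R] = plast.gamma_d_R
    pv[I_TH_P_R] = plast.theta_p_R
    pv[I_TH_D_R] = plast.theta_d_R
    return pv


def pack_flags(plast):
    f = 0
    if plast.learn_P:
        f |= F_LEARN_P
    if plast.learn_V:
        f |= F_LEARN_V
    if plast.learn_W:
        f |= F_LEARN_W
    if plast.learn_Q:
        f |= F_LEARN_Q
    if plast.learn_R:
        f |= F_LEARN_R
    return f


@njit(cache=True)
def simulate(
    x, y, z, ax, ay,
    P, V, W, Q, R,
    items, item_steps,
    bz, n_steps,
    pv, flags, seed,
    rec_stride, out_x, out_y, out_z,
):
    """Advance the full system ``n_steps`` Euler–Maruyama steps in place.

    ``items`` is the (n_items, M) array of input vectors; step ``k`` sees
    ``items[k // item_steps]`` while that index is in range and zero input
    afterwards (free run).  ``bz`` is the per-step chunking-layer bias.
    States are recorded every ``rec_stride`` steps into the ``out_*`` arrays.

    Returns 0 on success or 1 + the step index at which the state became
    non-finite.
    """
    np.random.seed(seed)
    N_X = x.shape[0]
    N_Y = y.shape[0]
    M = P.shape[0]
    n_items = items.shape[0]

    dt = pv[I_DT]
    sq = np.sqrt(dt)
    tau_x = pv[I_TAU_X]
    tau_y = pv[I_TAU_Y]
    tau_z = pv[I_TAU_Z]
    floor = pv[I_FLOOR]

    nx = np.empty(N_X)
    ny = np.empty(N_Y)
    inp = np.zeros(N_X)
    qrow = np.empty(N_X)

    learn_P = (flags & F_LEARN_P) != 0
    learn_V = (flags & F_LEARN_V) != 0
    learn_W = (flags & F_LEARN_W) != 0
    learn_Q = (flags & F_LEARN_Q) != 0
    learn_R = (flags & F_LEARN_R) != 0
    any_learning = learn_P or learn_V or learn_W or learn_Q or learn_R

    item_prev = -2
    for step in range(n_steps):
        item = step // item_steps if (n_items > 0 and step < n_items * item_steps) else -1
        has_input = item >= 0

        # input drive P^T s; refresh when the item changes or P is learning
        if has_input and (item != item_prev or learn_P):
            s = items[item]
            for i in range(N_X):
                acc = 0.0
                for k in range(M):
                    acc += P[k, i] * s[k]
                inp[i] = acc
        elif not has_input and item_prev != -1:
            for i in range(N_X):
                inp[i] = 0.0
        item_prev = item

        # --- dynamics increments (state at t, weights at t) ---
        for i in range(N_X):
            vin = 0.0
            for i2 in range(N_X):
                vin += V[i2, i] * x[i2]
            rin = 0.0
            for j in range(N_Y):
                rin += R[j, i] * y[j]
            drift = x[i] * (inp[i] + pv[I_B_X] - vin - rin)
            nxi = x[i] + (dt * drift + pv[I_SIG_X] * sq * np.random.normal()) / tau_x
            nx[i] = nxi if nxi > floor else floor

        for j in range(N_Y):
            nyj = y[j] + (dt * y[j] * (z[j] + pv[I_B_Y])
                          + pv[I_SIG_Y] * sq * np.random.normal()) / tau_y
            ny[j] = nyj if nyj > floor else floor

        for j in range(N_Y):
            drive = bz[step]
            for i in range(N_X):
                drive += Q[i, j] * x[i]
            for j2 in range(N_Y):
                drive -= W[j2, j] * y[j2]
            if tau_z > 0.0:
                z[j] += (dt / tau_z) * (-z[j] + drive)
            else:
                z[j] = drive

        # --- plasticity (reads state and traces at t) ---
        if any_learning:
            if learn_P and has_input:
                s = items[item]
                c = dt / pv[I_TAU_P]
                for i in range(N_X):
                    if x[i] > 1e-12:
                        cxi = c * x[i]
                        for k in range(M):
                            P[k, i] += cxi * (s[k] - P[k, i])

            if learn_V:
                c = dt / pv[I_TAU_V]
                for i in range(N_X):
                    for j in range(N_X):
                        if i == j:
                            continue
                        v = V[i, j]
                        d = pv[I_ALPHA_V] * (pv[I_V_HI] - v) * (pv[I_V_LO] - v) * (pv[I_V_MID] - v)
                        if x[i] * pv[I_A_PLUS] * ax[j] > pv[I_TH_P]:
                            d += pv[I_V_HI] - v
                        if pv[I_A_MINUS] * ax[i] * x[j] > pv[I_TH_D]:
                            d += pv[I_V_LO] - v
                        v += c * d
                        V[i, j] = v if v > 0.0 else 0.0

            if learn_W:
                c = dt / pv[I_TAU_W]
                for i in range(N_Y):
                    for j in range(N_Y):
                        if i == j:
                            continue
                        w = W[i, j]
                        d = pv[I_ALPHA_W] * (pv[I_W_HI] - w) * (pv[I_W_LO] - w) * (pv[I_W_MID] - w)
                        if y[i] * pv[I_A_PLUS] * ay[j] > pv[I_TH_P_W]:
                            d += pv[I_W_HI] - w
                        if pv[I_A_MINUS] * ay[i] * y[j] > pv[I_TH_D_W]:
                            d += pv[I_W_LO] - w
                        w += c * d
                        W[i, j] = w if w > 0.0 else 0.0

            if learn_Q:
                c = dt / pv[I_TAU_Q]
                for i in range(N_X):
                    acc = 0.0
                    for j in range(N_Y):
                        acc += Q[i, j]
                    ex = acc - pv[I_M_H]
                    qrow[i] = pv[I_EPS_H] * ex if ex > 0.0 else 0.0
                for i in range(N_X):
                    for j in range(N_Y):
                        q = Q[i, j]
                        d = pv[I_ALPHA_Q] * (pv[I_Q_HI] - q) * (pv[I_Q_LO] - q) * (pv[I_Q_MID] - q)
                        if x[i] * y[j] > pv[I_TH_P_Q]:
                            d += pv[I_GP_Q] * (pv[I_Q_HI] - q)
                        if y[j] > pv[I_TH_D_Q]:
                            d += pv[I_GD_Q] * (pv[I_Q_LO] - q)
                        d -= qrow[i]
                        q += c * d
                        Q[i, j] = q if q > 0.0 else 0.0

            if learn_R:
                c = dt / pv[I_TAU_R]
                for j in range(N_Y):
                    for i in range(N_X):
                        r = R[j, i]
                        d = pv[I_ALPHA_R] * (pv[I_R_HI] - r) * (pv[I_R_LO] - r) * (pv[I_R_MID] - r)
                        if x[i] * y[j] > pv[I_TH_P_R]:
                            d += pv[I_GP_R] * (pv[I_R_LO] - r)
                        if y[j] > pv[I_TH_D_R]:
                            d += pv[I_GD_R] * (pv[I_R_HI] - r)
                        r += c * d
                        R[j, i] = r if r > 0.0 else 0.0

        # --- traces (filter the activity at t) ---
        ca = dt / pv[I_TAU_A]
        for i in range(N_X):
            ax[i] += ca * (-ax[i] + pv[I_TAU_A] * x[i])
        cay = dt / pv[I_TAU_A_Y]
        for j in range(N_Y):
            ay[j] += cay * (-ay[j] + pv[I_TAU_A_Y] * y[j])

        # --- commit and record ---
        for i in range(N_X):
            x[i] = nx[i]
        for j in range(N_Y):
            y[j] = ny[j]

        if step % rec_stride == 0:
            r = step // rec_stride
            for i in range(N_X):
                out_x[r, i] = x[i]
            for j in range(N_Y):
                out_y[r, j] = y[j]
            for j in range(N_Y):
                out_z[r, j] = z[j]

        if step % 200 == 199:
            tot = 0.0
            for i in range(N_X):
                tot += x[i]
            for j in range(N_Y):
                tot += y[j] + z[j]
            if not np.isfinite(tot):
                return 1 + step
    return 0
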