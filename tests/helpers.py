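"""Independent oracles used by the test suite.

Everything here is deliberately written *against the model's equations*
rather than against the package's implementation: scalar term-by-term
transcription of the kinetics, a dense-matrix assembly of the radial
diffusion operator from its flux definition, and a scipy-based
method-of-steps integrator for the spatially lumped delay system.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

# field order must match the package's canonical order
FIELDS = ("R", "M", "F", "P", "U", "C", "S_T", "S_A", "D_N", "D_A")


def transcribed_rates(y, y1, y2, p):
    """Scalar, loop-based transcription of the reaction kinetics.

    ``y``, ``y1``, ``y2`` are (10, n) arrays (current, t - tau_1,
    t - tau_2); ``p`` exposes the parameter symbols as attributes.
    Written independently, one printed term at a time.
    """
    n = y.shape[1]
    out = np.empty_like(y)
    for j in range(n):
        R, M, F, P, U, C, ST, SA, DN, DA = (float(y[i, j]) for i in range(10))
        F1 = float(y1[2, j])
        ST1 = float(y1[6, j])
        R2 = float(y2[0, j])

        sat_M = M / (p.lambda_M + M)
        sat_F = F / (p.lambda_F + F)
        sat_P = P / (p.lambda_P + P)
        sat_F1 = F1 / (p.lambda_F + F1)
        sat_R2 = R2 / (p.lambda_R + R2)
        H = 1.0 if (P - p.P_c) < 0 else 0.0

        out[0, j] = -p.delta_R * R + p.sigma_R * ST
        out[1, j] = (-p.delta_M * M + p.sigma_M * DN
                     + p.delta_U * U * sat_F)
        out[2, j] = -p.delta_F * F + p.sigma_F * ST
        out[3, j] = (-p.delta_P * P
                     + p.sigma_P * C * sat_R2 * p.Lambda / (p.Lambda + F))
        out[4, j] = -p.delta_U * U * sat_F
        out[5, j] = (p.alpha * SA * sat_P
                     - p.beta_1 * C * sat_M * H
                     - p.beta_2 * C * sat_F * H)
        out[6, j] = (p.beta_1 * C * sat_M * H + p.beta_2 * C * sat_F * H
                     - p.gamma * ST1 * sat_F1
                     - p.nu * ST * sat_F * sat_M)
        out[7, j] = (p.gamma * ST1 * sat_F1 - p.alpha * SA * sat_P
                     - p.mu_SA * SA * sat_F)
        out[8, j] = -p.mu_DN * DN
        out[9, j] = (p.nu * ST * sat_F * sat_M + p.mu_SA * SA * sat_F)
    return out


def dense_radial_operator(r_max, n):
    """Dense matrix of the conservative radial diffusion operator.

    Assembled edge by edge from the finite-volume flux definition:
    flux through the annulus edge at radius ``e`` is
    ``2 pi e (u_outer - u_inner) / dr``; boundary edges carry none.
    """
    dr = r_max / n
    edges = np.array([i * dr for i in range(n + 1)])
    areas = np.array([np.pi * (edges[i + 1] ** 2 - edges[i] ** 2)
                      for i in range(n)])
    L = np.zeros((n, n))
    for i in range(1, n):  # interior edge between cells i-1 and i
        w = 2.0 * np.pi * edges[i] / dr
        L[i - 1, i - 1] -= w
        L[i - 1, i] += w
        L[i, i] -= w
        L[i, i - 1] += w
    return L / areas[:, None], areas


def lumped_dde_solution(y0, pre_history, p, t_end, t_eval,
                        rtol=1e-10, atol=1e-12):
    """Method-of-steps reference solution of the 10-variable lumped system.

    Integrates window by window with scipy's RK45 and dense output; the
    delayed arguments are evaluated from previously completed windows
    (or from the constant pre-initial history).  Used as the
    independent oracle for the spatially uniform limit of the PDE
    solver, in which diffusion vanishes identically.
    """
    y0 = np.asarray(y0, dtype=float)
    pre = np.asarray(pre_history, dtype=float)
    windows = []  # (t0, t1, OdeSolution)

    def value_at(t):
        if t <= 0:
            return pre
        for (a, b, sol) in windows:
            if a <= t <= b:
                return sol(t)
        raise AssertionError(f"no window covers t={t}")

    def rhs(t, y):
        y1 = value_at(t - p.tau_1)
        y2 = value_at(t - p.tau_2)
        return transcribed_rates(y[:, None], y1[:, None], y2[:, None],
                                 p)[:, 0]

    step = min(p.tau_1, p.tau_2)
    t = 0.0
    y = y0
    while t < t_end - 1e-12:
        t1 = min(t + step, t_end)
        sol = solve_ivp(rhs, (t, t1), y, method="RK45", rtol=rtol,
                        atol=atol, dense_output=True)
        assert sol.success, sol.message
        windows.append((t, t1, sol.sol))
        t, y = t1, sol.y[:, -1]

    return np.stack([value_at(te) if te > 0 else y0 for te in t_eval])


def scalar_delay_exact(t, tau=1.0):
    """Closed-form method-of-steps solution of u' = -u(t - tau), u = 1
    for t <= 0, valid on [0, 2 tau]."""
    t = np.asarray(t, dtype=float)
    out = np.where(t <= tau, 1.0 - t,
                   1.0 - t + 0.5 * (t - tau) ** 2)
    return out
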