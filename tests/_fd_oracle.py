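"""Independent finite-difference (box-scheme) oracle for the transformed
two-region ODE system.  Second-order implicit midpoint on a fine fixed
mesh, assembled as one sparse linear system — a discretisation wholly
different from the production collocation path."""

import numpy as np
import scipy.sparse as sps
from scipy.sparse.linalg import spsolve


def box_scheme_solve(coeffs, k, jump_type, n=3000):
    """Solve the fundamental BVP with a trapezoidal box scheme.

    Returns a dict with the state at the four tagged radii plus the
    stress traces at the tear radius, mirroring FundamentalSolution.
    """
    g = coeffs.base.geom
    h1, h2 = g.r_c - g.r_in, g.r_c - g.r_out
    t = np.linspace(0.0, 1.0, n + 1)
    r1 = g.r_in + t * h1
    r2 = g.r_out + t * h2
    F = np.zeros((n + 1, 8, 8))
    F[:, 0:4, 0:4] = h1 * np.moveaxis(coeffs.ode_matrix(r1, k), -1, 0)
    F[:, 4:8, 4:8] = h2 * np.moveaxis(coeffs.ode_matrix(r2, k), -1, 0)

    N = 8 * (n + 1)
    A = sps.lil_matrix((N, N))
    b = np.zeros(N)
    h = t[1] - t[0]
    I8 = np.eye(8)
    for i in range(n):
        rows = slice(8 * i, 8 * i + 8)
        A[rows, 8 * i: 8 * i + 8] = -I8 - h / 2 * F[i]
        A[rows, 8 * (i + 1): 8 * (i + 1) + 8] = I8 - h / 2 * F[i + 1]

    # boundary rows at t=0 (walls) and jump rows at t=1
    rr_in, rz_in = coeffs.stress_rows(g.r_in, k, coeffs.base.P_in)
    rr_out, rz_out = coeffs.stress_rows(g.r_out, k, g.P_ext)
    rr_c, rz_c = coeffs.trace_rows(g.r_c, k)
    if jump_type == "u":
        Ju, Jup = 1.0, -1.0 / g.r_c
    else:
        Ju, Jup = 0.0, k
    base = 8 * n
    A[base + 0, 0:4] = rr_in
    A[base + 1, 0:4] = rz_in
    A[base + 2, 4:8] = rr_out
    A[base + 3, 4:8] = rz_out
    end = slice(8 * n, 8 * n + 8)
    jrows = np.zeros((4, 8))
    jrows[0, 4], jrows[0, 0] = 1, -1
    jrows[1, 5], jrows[1, 1] = 1, -1
    jrows[2, 4:8], jrows[2, 0:4] = rr_c, -rr_c
    jrows[3, 4:8], jrows[3, 0:4] = rz_c, -rz_c
    for m in range(4):
        A[base + 4 + m, end] = jrows[m]
    b[base + 4] = Ju
    b[base + 5] = Jup

    y = spsolve(A.tocsr(), b).reshape(n + 1, 8)
    ya, yb = y[0], y[-1]
    eps = 1.0 if jump_type == "u" else -1.0

    def w_of(state, r):
        return -eps * (state[1] + state[0] / r) / k

    return {
        "U": {"rin": ya[0], "rout": ya[4], "rc-": yb[0], "rc+": yb[4]},
        "W": {"rin": w_of(ya[0:4], g.r_in), "rout": w_of(ya[4:8], g.r_out),
              "rc-": w_of(yb[0:4], g.r_c), "rc+": w_of(yb[4:8], g.r_c)},
        "S_rr": 0.5 * (rr_c @ yb[0:4] + rr_c @ yb[4:8]),
        "S_rz": 0.5 * (rz_c @ yb[0:4] + rz_c @ yb[4:8]),
        "n": n,
    }
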