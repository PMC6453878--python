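"""Fundamental (ring-dislocation) solutions of the incremental problem.

For each wavenumber k the incremental equilibrium equations, Fourier
transformed in z, reduce to a linear ODE system in the transformed radial
displacement U(r) and pressure increment qd(r):

    A1 U + B1 U' + C1 U'' + D1 U''' + E1 qd = 0        (axial equilibrium)
    A2 U + B2 U' + C2 U'' + D2 qd'          = 0        (radial equilibrium)

with the transformed axial displacement eliminated through
incompressibility, W = -eps (U' + U/r)/k (eps = +1 for a radial jump,
-1 for an axial jump).  The wall is split at the tear radius r_c into two
regions, each mapped onto t in [0, 1] with the wall boundary at t = 0 and
the tear face at t = 1, and the coupled 8-dimensional first-order system
is solved by collocation (scipy.integrate.solve_bvp) under the four
boundary conditions at the walls and four jump conditions at r_c:
[U], [U'] fixed by the prescribed unit displacement discontinuity, and
continuity of the transformed tractions [S_rr] = [S_rz] = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_bvp

from . import _symbolic
from .base_state import BaseState

__all__ = ["CoefficientSet", "FundamentalSolution", "derive_coefficient_functions",
           "solve_fundamental_bvp", "k_zero_solve"]

RADIUS_TAGS = ("rin", "rout", "rc-", "rc+")


class CollocationError(RuntimeError):
    """Raised when the two-point BVP collocation fails to converge."""


@dataclass
class CoefficientSet:
    """Numeric coefficient functions of the transformed ODE system.

    Wraps the computer-algebra output with the base-state pressure q(r)
    and its derivative; the same coefficients serve both jump problems.
    """

    base: BaseState
    _f: object = field(default=None, repr=False)

    def __post_init__(self):
        if self._f is None:
            self._f = _symbolic.ode_coefficient_callable()

    def _args(self, r, k):
        r = np.asarray(r, dtype=float)
        qv = self.base.q_at(r)
        qp = self.base.dq_at(r)
        return (r, k, qv, qp, *self.base.params.astuple(), *self.base.geom.geom_args())

    def all_coeffs(self, r, k: float) -> dict:
        vals = self._f(*self._args(r, k))
        r = np.asarray(r, dtype=float)
        return {nm: np.broadcast_to(np.asarray(v, float), r.shape).copy()
                if np.ndim(v) < np.ndim(r) else np.asarray(v, float)
                for nm, v in zip(_symbolic.ODE_COEFF_NAMES, vals)}

    def k0_coeffs(self, r) -> dict:
        """The coefficients that remain regular at k = 0."""
        f0 = _symbolic.ode_coefficient_k0_callable()
        r = np.asarray(r, dtype=float)
        args = self._args(r, 0.0)
        vals = f0(args[0], *args[2:])
        return {nm: np.asarray(v, float)
                for nm, v in zip(_symbolic.K0_COEFF_NAMES, vals)}

    def ode_matrix(self, r, k: float) -> np.ndarray:
        """First-order system matrix F with y' = F y, y = (U, U', U'', qd)."""
        c = self.all_coeffs(r, k)
        r = np.asarray(r, dtype=float)
        F = np.zeros((4, 4) + r.shape)
        F[0, 1] = 1.0
        F[1, 2] = 1.0
        F[2, 0] = -c["A1"] / c["D1"]
        F[2, 1] = -c["B1"] / c["D1"]
        F[2, 2] = -c["C1"] / c["D1"]
        F[2, 3] = -c["E1"] / c["D1"]
        F[3, 0] = -c["A2"] / c["D2"]
        F[3, 1] = -c["B2"] / c["D2"]
        F[3, 2] = -c["C2"] / c["D2"]
        return F

    def stress_rows(self, r: float, k: float, P: float) -> tuple[np.ndarray, np.ndarray]:
        """Rows (length 4) mapping y -> boundary residuals S_rr - P U' and
        S_rz + P k U at radius r under wall pressure P."""
        c = self.all_coeffs(np.asarray(r, float), k)
        row_rr = np.array([float(c["sr1"]), float(c["sr2"]) - P, 0.0, 1.0])
        row_rz = np.array([float(c["sz1"]) + P * k, float(c["sz2"]), float(c["sz3"]), 0.0])
        return row_rr, row_rz

    def trace_rows(self, r: float, k: float) -> tuple[np.ndarray, np.ndarray]:
        """Rows mapping y -> (S_rr, S_rz) amplitudes at radius r."""
        c = self.all_coeffs(np.asarray(r, float), k)
        return (np.array([float(c["sr1"]), float(c["sr2"]), 0.0, 1.0]),
                np.array([float(c["sz1"]), float(c["sz2"]), float(c["sz3"]), 0.0]))


def derive_coefficient_functions(base_state: BaseState, params=None) -> CoefficientSet:
    """Build the numeric coefficient set for a solved base state."""
    if params is not None and params != base_state.params:
        raise ValueError("params disagree with the base state's material")
    return CoefficientSet(base_state)


@dataclass
class FundamentalSolution:
    """Transformed response to a unit point displacement jump at r_c."""

    jump_type: str          # 'u' (radial) or 'w' (axial)
    k: float
    S_rr: float             # transformed incremental traction traces at r_c
    S_rz: float
    U: dict                 # radial displacement amplitude per radius tag
    W: dict                 # axial displacement amplitude per radius tag
    qd_jump: float          # post-hoc [qd] diagnostic (not imposed)
    jump_residuals: np.ndarray
    sol: object = field(default=None, repr=False)
    # k = 0 only: coefficients of the 1/k parts, lim_{k->0} k*U and k*W
    # (the radial-jump solution carries a uniform axial-flux mode W ~ V0/k)
    kU: dict | None = None
    kW: dict | None = None


def _jump_targets(jump_type: str, k: float, r_c: float) -> tuple[float, float, float]:
    """([U], [U'], eps) for the requested unit jump."""
    if jump_type == "u":
        return 1.0, -1.0 / r_c, +1.0
    if jump_type == "w":
        return 0.0, k, -1.0
    raise ValueError(f"unknown jump type {jump_type!r}")


def _package(coeffs: CoefficientSet, k: float, jump_type: str, sol) -> FundamentalSolution:
    g = coeffs.base.geom
    eps = _jump_targets(jump_type, k, g.r_c)[2]
    ya, yb = sol.y[:, 0], sol.y[:, -1]
    y_in, y_out = ya[0:4], ya[4:8]
    y_cm, y_cp = yb[0:4], yb[4:8]

    row_rr, row_rz = coeffs.trace_rows(g.r_c, k)
    S_rr = 0.5 * (row_rr @ y_cm + row_rr @ y_cp)
    S_rz = 0.5 * (row_rz @ y_cm + row_rz @ y_cp)

    def w_of(y, r):
        return -eps * (y[1] + y[0] / r) / k

    U = {"rin": y_in[0], "rout": y_out[0], "rc-": y_cm[0], "rc+": y_cp[0]}
    W = {"rin": w_of(y_in, g.r_in), "rout": w_of(y_out, g.r_out),
         "rc-": w_of(y_cm, g.r_c), "rc+": w_of(y_cp, g.r_c)}

    Ju, Jup, _ = _jump_targets(jump_type, k, g.r_c)
    jr = np.array([
        (y_cp[0] - y_cm[0]) - Ju,
        (y_cp[1] - y_cm[1]) - Jup,
        row_rr @ (y_cp - y_cm),
        row_rz @ (y_cp - y_cm),
    ])
    return FundamentalSolution(
        jump_type=jump_type, k=k, S_rr=float(S_rr), S_rz=float(S_rz),
        U={t: float(v) for t, v in U.items()}, W={t: float(v) for t, v in W.items()},
        qd_jump=float(y_cp[3] - y_cm[3]), jump_residuals=jr, sol=sol,
    )


def solve_fundamental_bvp(
    coeffs: CoefficientSet,
    k: float,
    jump_type: str,
    tol: float = 1e-8,
    init=None,
    max_nodes: int = 50000,
) -> FundamentalSolution:
    """Solve the two-region fundamental BVP at wavenumber k > 0.

    ``init`` may be a previous solution (continuation in k); its mesh and
    values seed the collocation.
    """
    if not k > 0:
        raise ValueError("k must be positive; use k_zero_solve for k = 0")
    g = coeffs.base.geom
    h1 = g.r_c - g.r_in
    h2 = g.r_c - g.r_out
    Ju, Jup, _ = _jump_targets(jump_type, k, g.r_c)

    def fun(t, y):
        r1 = g.r_in + t * h1
        r2 = g.r_out + t * h2
        F1 = coeffs.ode_matrix(r1, k)
        F2 = coeffs.ode_matrix(r2, k)
        dy = np.empty_like(y)
        dy[0:4] = h1 * np.einsum("ij...,j...->i...", F1, y[0:4])
        dy[4:8] = h2 * np.einsum("ij...,j...->i...", F2, y[4:8])
        return dy

    def fun_jac(t, y):
        r1 = g.r_in + t * h1
        r2 = g.r_out + t * h2
        J = np.zeros((8, 8, t.size))
        J[0:4, 0:4] = h1 * coeffs.ode_matrix(r1, k)
        J[4:8, 4:8] = h2 * coeffs.ode_matrix(r2, k)
        return J

    rr_in, rz_in = coeffs.stress_rows(g.r_in, k, coeffs.base.P_in)
    rr_out, rz_out = coeffs.stress_rows(g.r_out, k, g.P_ext)
    rr_c, rz_c = coeffs.trace_rows(g.r_c, k)

    Ba = np.zeros((8, 8))
    Bb = np.zeros((8, 8))
    rhs = np.zeros(8)
    Ba[0, 0:4], Ba[1, 0:4] = rr_in, rz_in          # wall conditions at t=0
    Ba[2, 4:8], Ba[3, 4:8] = rr_out, rz_out
    Bb[4, 4:8], Bb[4, 0:4] = [1, 0, 0, 0], [-1, 0, 0, 0]   # [U]
    Bb[5, 4:8], Bb[5, 0:4] = [0, 1, 0, 0], [0, -1, 0, 0]   # [U']
    Bb[6, 4:8], Bb[6, 0:4] = rr_c, -rr_c                   # [S_rr]
    Bb[7, 4:8], Bb[7, 0:4] = rz_c, -rz_c                   # [S_rz]
    rhs[4], rhs[5] = Ju, Jup

    def bc(ya, yb):
        return Ba @ ya + Bb @ yb - rhs

    def bc_jac(ya, yb):
        return Ba, Bb

    if init is not None and init.sol is not None:
        x0, y0 = init.sol.x, init.sol.y
    else:
        x0 = np.linspace(0.0, 1.0, 41)
        y0 = np.zeros((8, x0.size))

    sol = solve_bvp(fun, bc, x0, y0, fun_jac=fun_jac, bc_jac=bc_jac,
                    tol=tol, max_nodes=max_nodes)
    if sol.status != 0:
        raise CollocationError(
            f"fundamental BVP failed (k={k}, jump={jump_type}): {sol.message}; "
            f"mesh size {sol.x.size}"
        )
    return _package(coeffs, k, jump_type, sol)


def k_zero_solve(coeffs: CoefficientSet, jump_type: str,
                 k_seed: float = 2e-3) -> FundamentalSolution:
    """Fundamental solution in the degenerate k = 0 limit.

    At exactly k = 0 the transformed system is rank-deficient: the axial
    amplitude carries a rigid/flux mode (for the radial jump
    W ~ V0 / k with a uniform V0).  The regular parts of the solution are
    therefore obtained by k^2-Richardson extrapolation of the well-posed
    problem at two small wavenumbers, and the 1/k coefficients
    (lim k U, lim k W per radius) are extrapolated alongside and stored on
    the returned solution for the quadrature of the sine-type kernels.
    """
    f1 = solve_fundamental_bvp(coeffs, k_seed, jump_type, tol=1e-8)
    f2 = solve_fundamental_bvp(coeffs, k_seed / 2, jump_type, tol=1e-8, init=f1)

    def rich(a, b):
        return (4.0 * b - a) / 3.0

    tags = RADIUS_TAGS
    if jump_type == "u":
        U = {t: rich(f1.U[t], f2.U[t]) for t in tags}
        W = dict.fromkeys(tags, 0.0)
        kW = {t: rich(k_seed * f1.W[t], k_seed / 2 * f2.W[t]) for t in tags}
        kU = dict.fromkeys(tags, 0.0)
        S_rr = rich(f1.S_rr, f2.S_rr)
        S_rz = 0.0   # S_rz^u vanishes linearly in k
    elif jump_type == "w":
        U = dict.fromkeys(tags, 0.0)
        W = {t: rich(f1.W[t], f2.W[t]) for t in tags}
        kU = {t: rich(k_seed * f1.U[t], k_seed / 2 * f2.U[t]) for t in tags}
        kW = dict.fromkeys(tags, 0.0)
        S_rr = 0.0   # S_rr^w vanishes linearly in k
        S_rz = 0.0
    else:
        raise ValueError(f"unknown jump type {jump_type!r}")
    return FundamentalSolution(
        jump_type=jump_type, k=0.0, S_rr=float(S_rr), S_rz=float(S_rz),
        U=U, W=W, qd_jump=rich(f1.qd_jump, f2.qd_jump),
        jump_residuals=np.zeros(4), kU=kU, kW=kW,
    )
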