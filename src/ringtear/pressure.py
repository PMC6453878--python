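"""Axisymmetric response to an incremental lumen pressure.

A small rise Pdot of the blood pressure acts on the inner wall and on
both tear faces.  The z-independent part of the response is purely
radial; incompressibility forces du/dr = -u/r, hence u(r) = C/r across
the whole wall (the tear contributes no jump to this field), and the
pressure increment qdot follows from radial equilibrium by quadrature.
The resulting tear-face normal stress S_rr^P and surface displacements
u^P enter the tear problem additively: the tractions gain
-S_rr^P(r_c) Pdot and every surface displacement gains u^P Pdot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .base_state import BaseState
from .fundamental import derive_coefficient_functions

__all__ = ["PressureState", "solve_pressure_field", "pressure_kernel_terms"]


@dataclass
class PressureState:
    """Radial incremental field u = C/r, qdot(r), per applied Pdot."""

    base: BaseState
    Pdot: float
    C: float                  # u(r) = C / r  (mm * mm)
    qd_inner: float           # qdot at r_in

    def u_at(self, r):
        return self.C / np.asarray(r, float)

    def qd_at(self, r):
        co = derive_coefficient_functions(self.base)

        def slope(s):
            c = co.k0_coeffs(np.asarray(s, float))
            return float(-(c["A2"] / s - c["B2"] / s**2 + 2.0 * c["C2"] / s**3)
                         / c["D2"]) * self.C

        r = np.atleast_1d(np.asarray(r, float))
        out = np.array([self.qd_inner
                        + quad(slope, self.base.geom.r_in, ri, limit=200)[0]
                        for ri in r])
        return out[0] if np.isscalar(r) or out.size == 1 else out

    def S_rr_at(self, r):
        """Incremental normal stress of the pressure field (kPa)."""
        co = derive_coefficient_functions(self.base)
        r = np.asarray(r, float)
        c = co.k0_coeffs(r)
        return (c["sr1"] / r - c["sr2"] / r**2) * self.C + self.qd_at(r)

    def to_frame(self, n: int = 101) -> pd.DataFrame:
        g = self.base.geom
        r = np.linspace(g.r_in, g.r_out, n)
        return pd.DataFrame({"r": r, "u": self.u_at(r), "qdot": self.qd_at(r)})


def solve_pressure_field(base: BaseState, Pdot: float = 1.0) -> PressureState:
    """Solve the two-point problem for (C, qdot) under the boundary
    conditions  S_rr - P_in u' + Pdot = 0 at r_in  and
    S_rr - P_ext u' = 0 at r_out."""
    g = base.geom
    co = derive_coefficient_functions(base)

    def srow(r, P):
        c = co.k0_coeffs(np.asarray(r, float))
        # (S_rr - P u') per unit C with u = C/r
        return float(c["sr1"]) / r - float(c["sr2"]) / r**2 + P / r**2

    def slope_unit(s):
        c = co.k0_coeffs(np.asarray(s, float))
        return float(-(c["A2"] / s - c["B2"] / s**2 + 2.0 * c["C2"] / s**3) / c["D2"])

    G = quad(slope_unit, g.r_in, g.r_out, limit=200)[0]   # qd(r_out)-qd(r_in) per C
    # unknowns (C, qd_inner):
    M = np.array([
        [srow(g.r_in, base.P_in), 1.0],
        [srow(g.r_out, g.P_ext) + G, 1.0],
    ])
    b = np.array([-Pdot, 0.0])
    C, qd_in = np.linalg.solve(M, b)
    return PressureState(base=base, Pdot=Pdot, C=float(C), qd_inner=float(qd_in))


def pressure_kernel_terms(ps: PressureState, r_c: float) -> tuple[float, dict]:
    """Additive terms for the tear problem, per unit Pdot.

    Returns ``S_rr^P(r_c)`` and a dict surface tag -> u^P at that surface
    (the pressure field is continuous across the tear, so both faces see
    the same values).
    """
    if ps.Pdot != 1.0:
        raise ValueError("pressure kernel terms are defined per unit Pdot")
    g = ps.base.geom
    S_rr_P = float(ps.S_rr_at(r_c))
    u_P = {"rin": float(ps.u_at(g.r_in)), "rout": float(ps.u_at(g.r_out)),
           "rc-": float(ps.u_at(r_c)), "rc+": float(ps.u_at(r_c))}
    return S_rr_P, u_P
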