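"""Finite deformation of the closed, residually stressed, stretched tube.

The stress-free reference configuration is the opened sector
(R_in <= R <= R_out, opening angle alpha); closing it (kappa =
2 pi / (2 pi - alpha)), stretching axially by lambda and fixing the
deformed inner radius r_in determines the whole isochoric deformation

    R(r) = sqrt(kappa lambda (r^2 - r_in^2) + R_in^2),
    a_r = R/(kappa lambda r),  a_theta = kappa r / R,  a_z = lambda.

The single remaining (radial) equilibrium equation
d sigma_rr / dr = (sigma_tt - sigma_rr)/r is integrated inward from the
traction condition sigma_rr(r_out) = -P_ext; the Lagrange pressure q(r)
is recovered from the constitutive split and the lumen pressure that
maintains the configuration is P_in = -sigma_rr(r_in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson
from scipy.interpolate import CubicSpline

from . import _symbolic
from .material import DeformationGradientDiag, MaterialParams

__all__ = ["TubeGeometry", "BaseState", "radius_map", "deformation_gradient",
           "solve_radial_equilibrium"]


def kappa_from_alpha(alpha: float) -> float:
    """Opening-angle measure kappa = 2 pi / (2 pi - alpha)."""
    if not 0 <= alpha < 2 * np.pi:
        raise ValueError("opening angle alpha must lie in [0, 2*pi)")
    return 2 * np.pi / (2 * np.pi - alpha)


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry and loading of the closed tube (lengths mm, pressures kPa).

    ``r_out`` and ``R_in`` are user-specified; the reference outer radius
    ``R_out`` follows from incompressibility and is exposed as a property.
    """

    r_in: float
    r_out: float
    r_c: float
    R_in: float
    kappa: float = 1.0
    lam: float = 1.1
    P_ext: float = 0.0

    def __post_init__(self):
        if not 0 < self.r_in < self.r_c < self.r_out:
            raise ValueError("require 0 < r_in < r_c < r_out")
        if self.R_in <= 0:
            raise ValueError("reference inner radius must be positive")
        if self.kappa < 1.0:
            raise ValueError("kappa >= 1 required (opening angle >= 0)")
        if self.lam <= 0:
            raise ValueError("axial stretch must be positive")

    @property
    def R_out(self) -> float:
        """Reference outer radius implied by det A = 1 across the wall."""
        return radius_map(self, self.r_out)

    @property
    def alpha(self) -> float:
        return 2 * np.pi * (1 - 1 / self.kappa)

    def geom_args(self) -> tuple[float, float, float, float]:
        """(kappa, lam, r_in, R_in) in the symbolic-callable order."""
        return (self.kappa, self.lam, self.r_in, self.R_in)


def radius_map(geom: TubeGeometry, r) -> np.ndarray | float:
    """Reference radius R(r) of the material circle now at radius r."""
    r = np.asarray(r, dtype=float)
    if np.any(r < geom.r_in - 1e-12) or np.any(r > geom.r_out + 1e-12):
        raise ValueError("radius outside the wall [r_in, r_out]")
    R2 = geom.kappa * geom.lam * (r**2 - geom.r_in**2) + geom.R_in**2
    return np.sqrt(R2)[()] if np.ndim(r) == 0 else np.sqrt(R2)


def deformation_gradient(geom: TubeGeometry, r: float) -> DeformationGradientDiag:
    """Principal stretches diag(a_r, a_theta, a_z) at radius r."""
    R = float(radius_map(geom, r))
    a_theta = geom.kappa * r / R
    a_z = geom.lam
    return DeformationGradientDiag(1.0 / (a_theta * a_z), a_theta, a_z)


@dataclass(frozen=True)
class BaseState:
    """Solved finite-deformation state of the closed tube."""

    geom: TubeGeometry
    params: MaterialParams
    r: np.ndarray
    R: np.ndarray
    a_r: np.ndarray
    a_theta: np.ndarray
    a_z: np.ndarray
    q: np.ndarray
    sigma_rr: np.ndarray
    sigma_tt: np.ndarray
    sigma_zz: np.ndarray
    P_in: float
    _sig_spline: CubicSpline = field(repr=False)

    def sigma_rr_at(self, r) -> np.ndarray | float:
        return self._sig_spline(r)

    def q_at(self, r):
        """Lagrange pressure q(r) = sigma_rr - a_r dW/da_r."""
        f = _symbolic.base_profile_callables()["sig_rr_el"]
        return self._sig_spline(r) - f(r, *self.params.astuple(), *self.geom.geom_args())

    def dq_at(self, r):
        """Exact q'(r) from equilibrium and the closed-form elastic part."""
        fns = _symbolic.base_profile_callables()
        args = (*self.params.astuple(), *self.geom.geom_args())
        return fns["sig_diff"](r, *args) / r - fns["dsig_rr_el"](r, *args)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.r, "R": self.R,
                "a_r": self.a_r, "a_theta": self.a_theta, "a_z": self.a_z,
                "q": self.q, "sigma_rr": self.sigma_rr,
                "sigma_tt": self.sigma_tt, "sigma_zz": self.sigma_zz,
            }
        )


def solve_radial_equilibrium(
    geom: TubeGeometry, params: MaterialParams, n_grid: int = 2001
) -> BaseState:
    """Integrate radial equilibrium across the wall and assemble profiles.

    The q-free integrand sigma_tt - sigma_rr is available in closed form,
    so sigma_rr is a single cumulative quadrature (composite Simpson on a
    fine grid, spline-interpolated); a refinement check against a doubled
    grid guards the quadrature.
    """
    fns = _symbolic.base_profile_callables()
    args = (*params.astuple(), *geom.geom_args())
    r = np.linspace(geom.r_in, geom.r_out, n_grid)

    def sigma_rr_profile(rg):
        integrand = fns["sig_diff"](rg, *args) / rg
        cum = cumulative_simpson(integrand, x=rg, initial=0.0)
        # sigma_rr(r) = -P_ext - int_r^r_out (sig_tt - sig_rr)/s ds
        return -geom.P_ext - (cum[-1] - cum)

    sig_rr = sigma_rr_profile(r)
    sig_rr_fine = sigma_rr_profile(np.linspace(geom.r_in, geom.r_out, 2 * n_grid - 1))
    resid = abs(sig_rr_fine[0] - sig_rr[0])
    if resid > 1e-8:
        raise RuntimeError(
            f"radial-equilibrium quadrature did not converge: refinement "
            f"changes P_in by {resid:.3e} kPa (n_grid={n_grid})"
        )

    R = radius_map(geom, r)
    a_t = geom.kappa * r / R
    a_z = np.full_like(r, geom.lam)
    a_r = 1.0 / (a_t * a_z)
    sig_rr_el = fns["sig_rr_el"](r, *args)
    q = sig_rr - sig_rr_el
    sig_tt = sig_rr + fns["sig_diff"](r, *args)

    # sigma_zz from the constitutive split: a_z dW/da_z + q
    sig_zz = fns["sig_zz_el"](r, *args) + q

    spline = CubicSpline(r, sig_rr)
    return BaseState(
        geom=geom, params=params, r=r, R=R, a_r=a_r, a_theta=a_t, a_z=a_z,
        q=q, sigma_rr=sig_rr, sigma_tt=sig_tt, sigma_zz=sig_zz,
        P_in=float(-sig_rr[0]), _sig_spline=spline,
    )
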