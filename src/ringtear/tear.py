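"""Tear opening: tractions, densities, and surface profiles.

The dissection occupies r = r_c, |z| <= L.  Its faces carry the
incremental traction produced by connecting the tear to the lumen fluid,

    T_r = sigma_rr(r_in) - sigma_rr(r_c) - Pdot,     T_z = 0,

(a negative T_r is the face-opening, fluid-pressure sign in this
convention).  The piecewise-constant opening densities (U_j, W_j) solve
the 4N x 4N influence system; displacements anywhere follow from the
displacement influence matrices, and U_j itself is the local normal
opening of the faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .base_state import BaseState, TubeGeometry, solve_radial_equilibrium
from .fundamental import (CoefficientSet, derive_coefficient_functions,
                          k_zero_solve, solve_fundamental_bvp)
from .kernels import SURFACES, InfluenceSystem, assemble_systems
from .material import MaterialParams

__all__ = ["TearConfig", "TearSolution", "tear_tractions", "solve_opening",
           "evaluate_surface_displacements", "deformed_profiles", "max_width",
           "fundamental_sweep", "build_influence", "solve_tear"]


@dataclass(frozen=True)
class TearConfig:
    """Tear geometry and numerical controls.

    L        tear half-length (mm)
    N        half the number of tear elements (2N intervals of width L/N/... )
    k_max    wavenumber cutoff (1/mm)
    N_k      number of wavenumber steps (grid 0..k_max, step k_max/N_k)
    station_extent   displacement stations cover |z| <= station_extent * L
    bvp_tol  collocation tolerance of the fundamental solves
    """

    L: float = 2.0
    N: int = 20
    k_max: float = 10.0
    N_k: int = 300
    station_extent: int = 3
    bvp_tol: float = 1e-6

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("tear half-length must be positive")
        if self.N < 1:
            raise ValueError("need at least 2 tear intervals (N >= 1)")
        if self.k_max <= 0 or self.N_k < 10:
            raise ValueError("require k_max > 0 and N_k >= 10")

    @property
    def k_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.k_max, self.N_k + 1)


# per-process cache of fundamental sweeps, keyed by (base-state fingerprint,
# quadrature setting, jump type); sweeps are the dominant cost of a solve
_SWEEP_CACHE: dict = {}


def _base_key(base: BaseState) -> tuple:
    g, p = base.geom, base.params
    return (p.c, p.k1, p.k2, p.beta, g.r_in, g.r_out, g.r_c, g.R_in,
            g.kappa, g.lam, g.P_ext)


def fundamental_sweep(coeffs: CoefficientSet, cfg: TearConfig, jump_type: str,
                      use_cache: bool = True) -> list:
    """Fundamental solutions on the uniform k grid (k = 0 included).

    Solves ascending in k with continuation; results are cached per base
    state and quadrature setting.
    """
    key = (_base_key(coeffs.base), cfg.k_max, cfg.N_k, cfg.bvp_tol, jump_type)
    if use_cache and key in _SWEEP_CACHE:
        return _SWEEP_CACHE[key]
    out = [k_zero_solve(coeffs, jump_type)]
    prev = None
    for k in cfg.k_grid[1:]:
        prev = solve_fundamental_bvp(coeffs, float(k), jump_type,
                                     tol=cfg.bvp_tol, init=prev)
        out.append(prev)
    # drop collocation meshes before caching: traces only
    out = [replace(f, sol=None) for f in out]
    if use_cache:
        _SWEEP_CACHE[key] = out
    return out


def build_influence(base: BaseState, cfg: TearConfig,
                    use_cache: bool = True) -> InfluenceSystem:
    coeffs = derive_coefficient_functions(base)
    fu = fundamental_sweep(coeffs, cfg, "u", use_cache)
    fw = fundamental_sweep(coeffs, cfg, "w", use_cache)
    return assemble_systems(fu, fw, cfg)


def tear_tractions(base: BaseState, cfg: TearConfig, Pdot: float = 0.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Constant normal traction on every element; zero shear."""
    if Pdot < 0:
        raise ValueError("incremental pressure must be nonnegative")
    T = float(base.sigma_rr_at(base.geom.r_in) - base.sigma_rr_at(base.geom.r_c)) - Pdot
    n = 2 * cfg.N
    return np.full(n, T), np.zeros(n)


def solve_opening(influence: InfluenceSystem, tractions) -> tuple[np.ndarray, np.ndarray]:
    """Solve the dense 4N system for the opening densities (U_j, W_j)."""
    T_r, T_z = tractions
    n = influence.n_elements
    if T_r.size != n or T_z.size != n:
        raise ValueError("traction vectors inconsistent with the element count")
    A = influence.traction_matrix()
    b = np.concatenate([T_r, T_z])
    x = np.linalg.solve(A, b)
    resid = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300)
    if not np.isfinite(x).all() or (np.linalg.norm(b) > 0 and resid > 1e-10):
        raise RuntimeError(
            f"influence system solve failed: relative residual {resid:.2e}, "
            f"condition estimate {np.linalg.cond(A):.2e}"
        )
    return x[:n], x[n:]


@dataclass
class TearSolution:
    """Opening densities and surface displacement profiles."""

    config: TearConfig
    base: BaseState
    U: np.ndarray                     # normal opening per element (mm)
    W: np.ndarray                     # tangential opening per element (mm)
    T_r: float                        # applied normal traction (kPa)
    Pdot: float
    profiles: dict = field(repr=False)   # surface -> DataFrame(z, u, w)
    influence: InfluenceSystem = field(default=None, repr=False)

    @property
    def max_width(self) -> float:
        return max_width(self)

    def opening_profile(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.influence.centers, "U": self.U, "W": self.W})


def evaluate_surface_displacements(
    influence: InfluenceSystem, U: np.ndarray, W: np.ndarray,
    pressure_terms: dict | None = None, Pdot: float = 0.0,
) -> dict:
    """Displacement profiles u(z), w(z) on the walls and tear faces.

    ``pressure_terms`` maps surface tag -> radial displacement per unit
    incremental pressure (the z-independent pressure response), added as
    u += u^P * Pdot.
    """
    dens = np.concatenate([U, W])
    out = {}
    for s in SURFACES:
        Du, Dw = influence.displacement_matrices(s)
        u = Du @ dens
        w = Dw @ dens
        if pressure_terms is not None and Pdot != 0.0:
            u = u + pressure_terms[s] * Pdot
        out[s] = pd.DataFrame({"z": influence.stations, "u": u, "w": w})
    return out


def max_width(tsol: TearSolution) -> float:
    """Maximum normal opening of the tear faces, max_j U_j (mm).

    The density U is itself the local jump u(r_c+) - u(r_c-); for a
    face-compressing traction the solver reports the (negative) overlap.
    """
    return float(np.max(tsol.U))


def deformed_profiles(tsol: TearSolution, magnification: float = 1.0) -> dict:
    """Surface positions r + mag*u, z + mag*w for plotting/tabulation."""
    g = tsol.base.geom
    r_of = {"rin": g.r_in, "rout": g.r_out, "rc-": g.r_c, "rc+": g.r_c}
    out = {}
    for s, df in tsol.profiles.items():
        out[s] = pd.DataFrame({
            "z": df["z"] + magnification * df["w"],
            "r": r_of[s] + magnification * df["u"],
            "r_base": r_of[s],
            "u": df["u"], "w": df["w"],
        })
    return out


def solve_tear(
    geom: TubeGeometry,
    params: MaterialParams,
    cfg: TearConfig = TearConfig(),
    Pdot: float = 0.0,
    base: BaseState | None = None,
    use_cache: bool = True,
) -> TearSolution:
    """Full pipeline: base state -> influence system -> opening -> profiles."""
    if base is None:
        base = solve_radial_equilibrium(geom, params)
    influence = build_influence(base, cfg, use_cache)
    T_r_vec, T_z_vec = tear_tractions(base, cfg, Pdot)

    pressure_terms = None
    if Pdot != 0.0:
        from .pressure import pressure_kernel_terms, solve_pressure_field
        ps = solve_pressure_field(base, Pdot=1.0)
        S_rr_P, u_P = pressure_kernel_terms(ps, geom.r_c)
        T_r_vec = T_r_vec - S_rr_P * Pdot
        pressure_terms = u_P

    U, W = solve_opening(influence, (T_r_vec, T_z_vec))
    profiles = evaluate_surface_displacements(influence, U, W, pressure_terms, Pdot)
    return TearSolution(config=cfg, base=base, U=U, W=W,
                        T_r=float(T_r_vec[0]), Pdot=Pdot,
                        profiles=profiles, influence=influence)
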