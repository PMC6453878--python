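"""HGO constitutive law for the arterial media.

The wall is an incompressible fibre-reinforced solid: an isotropic
neo-Hookean ground matrix of stiffness ``c`` plus two families of collagen
fibres wound helically at angles +/-beta from the circumferential
direction, each contributing an exponential strain energy controlled by a
stiffness ``k1`` and a dimensionless exponent ``k2``.  All stresses are in
kPa, angles in radians.

Derivatives of the energy (nominal stress, incremental moduli) come from
the computer-algebra pipeline in :mod:`ringtear._symbolic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _symbolic

__all__ = [
    "MaterialParams",
    "DeformationGradientDiag",
    "IncrementalGradient",
    "fibre_tensors",
    "invariants",
    "strain_energy",
    "nominal_stress",
    "cauchy_stress",
    "incremental_moduli",
    "incremental_nominal_stress",
]

_DET_TOL = 1e-10
_EXP_GUARD = 700.0


class InvalidStateError(ValueError):
    """Raised for kinematic states that violate a model constraint."""


@dataclass(frozen=True)
class MaterialParams:
    """HGO constants: matrix stiffness c (kPa), fibre stiffness k1 (kPa),
    fibre exponent k2 (-), fibre angle beta (rad, from circumferential)."""

    c: float
    k1: float
    k2: float
    beta: float

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError("matrix stiffness c must be positive")
        if self.k1 < 0:
            raise ValueError("fibre stiffness k1 must be nonnegative")
        if not self.k2 > 0:
            raise ValueError("fibre exponent k2 must be positive")
        if not 0 <= self.beta <= np.pi / 2:
            raise ValueError("fibre angle beta must lie in [0, pi/2]")

    def astuple(self):
        return (self.c, self.k1, self.k2, self.beta)


@dataclass(frozen=True)
class DeformationGradientDiag:
    """Diagonal principal stretches (a_r, a_theta, a_z), det = 1."""

    a_r: float
    a_theta: float
    a_z: float

    def __post_init__(self):
        det = self.a_r * self.a_theta * self.a_z
        if abs(det - 1.0) > _DET_TOL:
            raise InvalidStateError(
                f"deformation gradient is not unimodular: det = {det!r}"
            )

    def as_matrix(self) -> np.ndarray:
        return np.diag([self.a_r, self.a_theta, self.a_z])


@dataclass(frozen=True)
class IncrementalGradient:
    """Components of the incremental displacement gradient.

    Layout (r, theta, z):  [[u_r, 0, u_z], [0, u/r, 0], [w_r, 0, w_z]];
    incompressibility requires a traceless gradient.
    """

    u_r: float
    u_z: float
    w_r: float
    w_z: float
    u_over_r: float

    def __post_init__(self):
        tr = self.u_r + self.u_over_r + self.w_z
        if abs(tr) > 1e-10 * max(1.0, abs(self.u_r), abs(self.w_z)):
            raise InvalidStateError(f"incremental gradient has trace {tr!r}")

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.u_r, 0.0, self.u_z],
                [0.0, self.u_over_r, 0.0],
                [self.w_r, 0.0, self.w_z],
            ]
        )


def fibre_tensors(beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Structure tensors M+- = m+- (x) m+- of the two fibre families.

    ``m+- = (0, cos beta, +-sin beta)`` in cylindrical polars; each tensor
    is symmetric, rank one and has unit trace.
    """
    if not 0 <= beta <= np.pi / 2:
        raise ValueError("fibre angle beta must lie in [0, pi/2]")
    cb, sb = np.cos(beta), np.sin(beta)
    Mp = np.array([[0, 0, 0], [0, cb**2, cb * sb], [0, cb * sb, sb**2]])
    Mm = np.array([[0, 0, 0], [0, cb**2, -cb * sb], [0, -cb * sb, sb**2]])
    return Mp, Mm


def invariants(A: DeformationGradientDiag, beta: float) -> tuple[float, float, float]:
    """(I1bar, I4bar, I6bar) for a diagonal deformation gradient.

    I1bar = tr(A^T A); I4bar/I6bar are the squared fibre stretches
    a_theta^2 cos^2(beta) + a_z^2 sin^2(beta) (equal for the two families).
    """
    F = A.as_matrix()
    C = F.T @ F
    Mp, Mm = fibre_tensors(beta)
    return float(np.trace(C)), float(np.trace(Mp @ C)), float(np.trace(Mm @ C))


def _flat_args(F: np.ndarray, params: MaterialParams):
    return list(np.asarray(F, dtype=float).ravel()) + list(params.astuple())


def strain_energy(params: MaterialParams, A: DeformationGradientDiag) -> float:
    """Strain energy density (kPa) at a unimodular diagonal state."""
    _, I4, I6 = invariants(A, params.beta)
    for name, val in (("I4bar", I4), ("I6bar", I6)):
        if params.k2 * (val - 1.0) ** 2 > _EXP_GUARD:
            raise OverflowError(
                f"fibre energy overflow: k2*({name}-1)^2 = "
                f"{params.k2 * (val - 1.0) ** 2:.3g} exceeds the exp guard"
            )
    fW, _ = _symbolic.energy_callables()
    return float(fW(*_flat_args(A.as_matrix(), params)))


def _dW(params: MaterialParams, F: np.ndarray) -> np.ndarray:
    _, fdW = _symbolic.energy_callables()
    return np.asarray(fdW(*_flat_args(F, params)), dtype=float)


def nominal_stress(params: MaterialParams, A, q: float) -> np.ndarray:
    """Nominal stress S_{alpha j} = dW/dA_{j alpha} + q B_{j alpha}, B = A^-T.

    ``A`` may be a :class:`DeformationGradientDiag` or any (invertible)
    3x3 array; the general form is needed by the finite-difference test
    oracles that perturb off-diagonal entries.
    """
    F = A.as_matrix() if isinstance(A, DeformationGradientDiag) else np.asarray(A, float)
    if abs(np.linalg.det(F)) < 1e-12:
        raise InvalidStateError("singular deformation gradient")
    dW = _dW(params, F)
    return dW.T + q * np.linalg.inv(F)


def cauchy_stress(params: MaterialParams, A, q: float) -> np.ndarray:
    """Cauchy stress sigma = A S (symmetric for any admissible state)."""
    F = A.as_matrix() if isinstance(A, DeformationGradientDiag) else np.asarray(A, float)
    return F @ nominal_stress(params, A, q)


def incremental_moduli(params: MaterialParams, A: DeformationGradientDiag) -> np.ndarray:
    """Push-forward incremental moduli A0_{ijkl} (shape (3,3,3,3), kPa).

    A0_{ijkl} = A_{i alpha} A_{k beta} d2W / dA_{j alpha} dA_{l beta}
    evaluated on the diagonal base state; possesses the major symmetry
    A0_{ijkl} = A0_{klij}.
    """
    f = _symbolic.moduli_diag_callable()
    vals = f(A.a_r, A.a_theta, A.a_z, *params.astuple())
    return np.asarray(vals, dtype=float).reshape(3, 3, 3, 3)


def incremental_nominal_stress(
    moduli: np.ndarray, q: float, dq: float, dA0: IncrementalGradient | np.ndarray
) -> np.ndarray:
    """Incremental nominal stress Sdot0_{ij}.

    Sdot0_{ij} = A0_{ijkl} dA0_{lk} - q dA0_{ij} + dq delta_{ij}; linear in
    the (traceless) incremental gradient and in the pressure increment.
    """
    G = dA0.as_matrix() if isinstance(dA0, IncrementalGradient) else np.asarray(dA0, float)
    if abs(np.trace(G)) > 1e-10 * max(1.0, np.abs(G).max()):
        raise InvalidStateError("incremental gradient must be traceless")
    return np.einsum("ijkl,lk->ij", moduli, G) - q * G + dq * np.eye(3)
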