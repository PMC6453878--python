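"""Constitutive law: invariants, stresses, moduli vs independent oracles."""

import itertools

import numpy as np
import pytest

from ringtear import _symbolic
from ringtear.material import (DeformationGradientDiag, IncrementalGradient,
                               InvalidStateError, MaterialParams,
                               cauchy_stress, fibre_tensors,
                               incremental_moduli, incremental_nominal_stress,
                               invariants, nominal_stress, strain_energy)

from conftest import random_unimodular_diag

IDENT = DeformationGradientDiag(1.0, 1.0, 1.0)


@pytest.mark.parametrize("beta,tt,zz,tz", [
    (0.0, 1.0, 0.0, 0.0),                       # circumferential fibres
    (np.pi / 2, 0.0, 1.0, 0.0),                 # axial fibres
    (np.pi / 3, 0.25, 0.75, np.sqrt(3) / 4),    # exact trigonometry
])
def test_fibre_tensor_entries(beta, tt, zz, tz):
    Mp, Mm = fibre_tensors(beta)
    for M, sgn in ((Mp, 1), (Mm, -1)):
        assert M[1, 1] == pytest.approx(tt, abs=1e-15)
        assert M[2, 2] == pytest.approx(zz, abs=1e-15)
        assert M[1, 2] == pytest.approx(sgn * tz, abs=1e-15)
        assert np.allclose(M, M.T)
        assert np.trace(M) == pytest.approx(1.0)
        assert np.linalg.matrix_rank(M, tol=1e-12) == 1
        assert np.allclose(M[0], 0)


def test_invariants_identity_and_closed_form():
    assert invariants(IDENT, 0.7) == pytest.approx((3.0, 1.0, 1.0))
    # tube state: a_theta = kappa r / R(r), a_z = lam at r = 5
    r, r_in, R_in, lam = 5.0, 4.0, 3.9, 1.1
    R = np.sqrt(lam * (r**2 - r_in**2) + R_in**2)
    a_t, a_z = r / R, lam
    A = DeformationGradientDiag(1 / (a_t * a_z), a_t, a_z)
    beta = np.pi / 3
    I1, I4, I6 = invariants(A, beta)
    assert I1 == pytest.approx(A.a_r**2 + a_t**2 + a_z**2, rel=1e-12)
    expected_I4 = a_t**2 * np.cos(beta) ** 2 + a_z**2 * np.sin(beta) ** 2
    assert I4 == pytest.approx(expected_I4, rel=1e-12)
    # cross-check by the full trace tr(M A^T A)
    Mp, _ = fibre_tensors(beta)
    F = A.as_matrix()
    assert I4 == pytest.approx(float(np.trace(Mp @ F.T @ F)), rel=1e-14)
    assert I4 == pytest.approx(I6, rel=1e-14)


def test_invariants_equal_for_both_families_randomly():
    rng = np.random.default_rng(7)
    for _ in range(50):
        A = random_unimodular_diag(rng)
        beta = rng.uniform(0, np.pi / 2)
        _, I4, I6 = invariants(A, beta)
        assert I4 == pytest.approx(I6, rel=1e-13)


def test_strain_energy_identity_and_neo_hookean_limit():
    p = MaterialParams(3.0, 2.3632, 0.8393, np.pi / 3)
    assert strain_energy(p, IDENT) == pytest.approx(0.0, abs=1e-14)
    p0 = MaterialParams(c=2.0, k1=1e-15, k2=1.0, beta=0.3)
    A = DeformationGradientDiag(0.5, 2.0, 1.0)
    assert strain_energy(p0, A) == pytest.approx(0.5 * 2.0 * (4 + 0.25 + 1 - 3),
                                                 rel=1e-9)


def test_strain_energy_positive_away_from_identity():
    p = MaterialParams(3.0, 2.3632, 0.8393, np.pi / 3)
    rng = np.random.default_rng(3)
    for _ in range(30):
        A = random_unimodular_diag(rng)
        if max(abs(A.a_r - 1), abs(A.a_theta - 1), abs(A.a_z - 1)) > 1e-3:
            assert strain_energy(p, A) > 0


def test_strain_energy_overflow_guard_names_invariant():
    p = MaterialParams(3.0, 2.3632, 10.0, 0.0)
    A = DeformationGradientDiag(1 / 100.0, 10.0, 10.0)
    with pytest.raises(OverflowError, match="I4bar|I6bar"):
        strain_energy(p, A)


def test_nominal_stress_isotropic_identity():
    p = MaterialParams(c=2.5, k1=1e-15, k2=1.0, beta=0.4)
    S = nominal_stress(p, IDENT, q=1.3)
    assert np.allclose(S, (2.5 + 1.3) * np.eye(3), atol=1e-12)


def test_nominal_stress_matches_finite_differences():
    """S_alpha_j = dW/dA_j_alpha + q B_j_alpha against central FD of W."""
    p = MaterialParams(3.0, 2.3632, 0.8393, np.pi / 3)
    fW, _ = _symbolic.energy_callables()
    rng = np.random.default_rng(11)
    h = 1e-6
    for _ in range(20):
        A = random_unimodular_diag(rng)
        F = A.as_matrix()
        q = rng.normal()
        S = nominal_stress(p, F, q)
        Sel = S - q * np.linalg.inv(F)
        for m, n in itertools.product(range(3), range(3)):
            Fp, Fm = F.copy(), F.copy()
            Fp[m, n] += h
            Fm[m, n] -= h
            fd = (fW(*Fp.ravel(), *p.astuple()) - fW(*Fm.ravel(), *p.astuple())) / (2 * h)
            assert Sel[n, m] == pytest.approx(fd, rel=1e-6, abs=1e-8)


def test_cauchy_stress_symmetric_and_consistent():
    p = MaterialParams(3.0, 2.3632, 0.8393, np.pi / 3)
    rng = np.random.default_rng(5)
    for _ in range(30):
        A = random_unimodular_diag(rng)
        q = rng.normal()
        S = nominal_stress(p, A, q)
        sig = cauchy_stress(p, A, q)
        assert np.allclose(sig, A.as_matrix() @ S, rtol=1e-13)
        assert np.allclose(sig, sig.T, atol=1e-10 * max(1, abs(sig).max()))


def test_fibre_stress_vanishes_at_unit_fibre_stretch():
    # a_theta^2 cos^2 b + a_z^2 sin^2 b = 1 with b = pi/4: a_t^2 + a_z^2 = 2
    a_t = 1.1
    a_z = np.sqrt(2 - a_t**2)
    A = DeformationGradientDiag(1 / (a_t * a_z), a_t, a_z)
    beta = np.pi / 4
    p_fib = MaterialParams(3.0, 2.3632, 0.8393, beta)
    p_iso = MaterialParams(3.0, 1e-15, 0.8393, beta)
    _, I4, I6 = invariants(A, beta)
    assert I4 == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(cauchy_stress(p_fib, A, 0.0), cauchy_stress(p_iso, A, 0.0),
                       atol=1e-10)


def test_incremental_moduli_neo_hookean_identity():
    p = MaterialParams(c=2.0, k1=1e-15, k2=1.0, beta=0.3)
    mod = incremental_moduli(p, IDENT)
    expect = 2.0 * np.einsum("ik,jl->ijkl", np.eye(3), np.eye(3))
    assert np.allclose(mod, expect, atol=1e-12)


def test_incremental_moduli_match_second_differences():
    """Push-forward moduli vs central FD of the elastic nominal stress.

    A0_{ijkl} = A_ii A_kk dS_{ij}/dA_{lk} on a diagonal state (no q part).
    """
    p = MaterialParams(3.0, 2.3632, 0.8393, np.pi / 3)
    rng = np.random.default_rng(2)
    h = 1e-5
    for _ in range(5):
        A = random_unimodular_diag(rng, spread=0.25)
        F = A.as_matrix()
        mod = incremental_moduli(p, A)
        scale = np.abs(mod).max()
        for l, k in itertools.product(range(3), range(3)):
            Fp, Fm = F.copy(), F.copy()
            Fp[l, k] += h
            Fm[l, k] -= h
            dS = (nominal_stress(p, Fp, 0.0) - nominal_stress(p, Fm, 0.0)) / (2 * h)
            for i, j in itertools.product(range(3), range(3)):
                ref = F[i, i] * F[k, k] * dS[i, j]
                assert mod[i, j, k, l] == pytest.approx(
                    ref, rel=1e-6, abs=1e-6 * scale)


def test_moduli_major_symmetry_and_finiteness(base_ref, params_ref):
    for r in np.linspace(base_ref.geom.r_in, base_ref.geom.r_out, 7):
        from ringtear.base_state import deformation_gradient
        A = deformation_gradient(base_ref.geom, r)
        mod = incremental_moduli(params_ref, A)
        assert np.isfinite(mod).all()
        assert np.allclose(mod, np.transpose(mod, (2, 3, 0, 1)), rtol=1e-12)


def test_moduli_smooth_across_wall(base_ref, params_ref):
    """No sign flips of the diagonal entries across the wall."""
    from ringtear.base_state import deformation_gradient
    rs = np.linspace(base_ref.geom.r_in, base_ref.geom.r_out, 25)
    diags = np.array([
        [incremental_moduli(params_ref, deformation_gradient(base_ref.geom, r))[i, j, i, j]
         for (i, j) in ((0, 0), (1, 1), (2, 2), (0, 2), (2, 0))]
        for r in rs
    ])
    assert (np.sign(diags) == np.sign(diags[0])).all()


def test_incremental_nominal_stress_pressure_and_linearity():
    p = MaterialParams(3.0, 2.3632, 0.8393, np.pi / 3)
    mod = incremental_moduli(p, IDENT)
    zero = IncrementalGradient(0, 0, 0, 0, 0)
    assert np.allclose(incremental_nominal_stress(mod, -1.0, 0.7, zero),
                       0.7 * np.eye(3))
    dA = IncrementalGradient(u_r=0.1, u_z=0.3, w_r=-0.2, w_z=0.15, u_over_r=-0.25)
    S1 = incremental_nominal_stress(mod, -1.0, 0.5, dA)
    dA2 = IncrementalGradient(0.2, 0.6, -0.4, 0.3, -0.5)
    S2 = incremental_nominal_stress(mod, -1.0, 1.0, dA2)
    assert np.allclose(2 * S1, S2, rtol=1e-13)


def test_incremental_nominal_stress_contraction_order():
    """A0_{ijkl} dA0_{lk}: verify against an explicit index loop."""
    p = MaterialParams(3.0, 2.3632, 0.8393, np.pi / 3)
    A = DeformationGradientDiag(1 / 1.21, 1.1, 1.1)
    mod = incremental_moduli(p, A)
    G = IncrementalGradient(0.1, 0.3, -0.2, 0.15, -0.25)
    got = incremental_nominal_stress(mod, -0.8, 0.4, G)
    Gm = G.as_matrix()
    ref = np.zeros((3, 3))
    for i, j in itertools.product(range(3), range(3)):
        ref[i, j] = sum(mod[i, j, k, l] * Gm[l, k]
                        for k in range(3) for l in range(3))
        ref[i, j] += -(-0.8) * Gm[i, j] + 0.4 * (i == j)
    assert np.allclose(got, ref, rtol=1e-13)


def test_invalid_states_raise():
    with pytest.raises(InvalidStateError):
        DeformationGradientDiag(1.0, 1.0, 1.5)
    with pytest.raises(InvalidStateError):
        IncrementalGradient(0.1, 0, 0, 0.1, 0.1)
    mod = incremental_moduli(MaterialParams(3, 2.3632, 0.8393, 1.0), IDENT)
    with pytest.raises(InvalidStateError):
        incremental_nominal_stress(mod, 0.0, 0.0, np.eye(3))
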