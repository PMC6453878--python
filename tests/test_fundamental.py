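"""Fundamental jump solutions: jump conditions, oracles, limits, decay."""

import numpy as np
import pytest

from ringtear.fundamental import (derive_coefficient_functions, k_zero_solve,
                                  solve_fundamental_bvp)
from ringtear.base_state import TubeGeometry, solve_radial_equilibrium
from ringtear.material import MaterialParams

from _fd_oracle import box_scheme_solve


@pytest.mark.parametrize("jump_type,k", [("u", 1.0), ("u", 5.0),
                                         ("w", 1.0), ("w", 5.0)])
def test_imposed_jump_and_continuity_conditions(coeffs_ref, jump_type, k):
    f = solve_fundamental_bvp(coeffs_ref, k, jump_type, tol=1e-8)
    assert np.abs(f.jump_residuals).max() < 1e-8
    # the prescribed displacement jumps, read back from the two faces
    if jump_type == "u":
        assert f.U["rc+"] - f.U["rc-"] == pytest.approx(1.0, abs=1e-8)
        assert f.W["rc+"] - f.W["rc-"] == pytest.approx(0.0, abs=1e-8)
    else:
        assert f.U["rc+"] - f.U["rc-"] == pytest.approx(0.0, abs=1e-8)
        assert f.W["rc+"] - f.W["rc-"] == pytest.approx(1.0, abs=1e-8)


def test_qdot_jump_reported_not_imposed(coeffs_ref):
    """[qd] is determined by the four imposed conditions and generally
    nonzero; it is exposed as a diagnostic."""
    f = solve_fundamental_bvp(coeffs_ref, 1.0, "w", tol=1e-8)
    assert np.isfinite(f.qd_jump)


@pytest.mark.parametrize("jump_type,k", [("u", 1.5), ("w", 2.5)])
def test_against_box_scheme_oracle(coeffs_ref, jump_type, k):
    """Collocation agrees with an independent FD discretisation to 1e-5."""
    f = solve_fundamental_bvp(coeffs_ref, k, jump_type, tol=1e-8)
    fd = box_scheme_solve(coeffs_ref, k, jump_type, n=4000)
    scale = max(abs(fd["S_rr"]), abs(fd["S_rz"]), 1.0)
    assert f.S_rr == pytest.approx(fd["S_rr"], abs=1e-5 * scale)
    assert f.S_rz == pytest.approx(fd["S_rz"], abs=1e-5 * scale)
    for tag in ("rin", "rout", "rc-", "rc+"):
        assert f.U[tag] == pytest.approx(fd["U"][tag], abs=1e-5)
        assert f.W[tag] == pytest.approx(fd["W"][tag], abs=1e-5)


def test_k_zero_continuous_with_small_k(coeffs_ref):
    f0u = k_zero_solve(coeffs_ref, "u")
    fsu = solve_fundamental_bvp(coeffs_ref, 1e-3, "u", tol=1e-8)
    assert f0u.S_rr == pytest.approx(fsu.S_rr, abs=1e-4)
    for tag in ("rin", "rout", "rc-", "rc+"):
        assert f0u.U[tag] == pytest.approx(fsu.U[tag], abs=1e-4)
        # the 1/k axial-flux coefficient reproduces the diverging W
        assert f0u.kW[tag] / 1e-3 == pytest.approx(fsu.W[tag], rel=2e-2)
    f0w = k_zero_solve(coeffs_ref, "w")
    fsw = solve_fundamental_bvp(coeffs_ref, 1e-3, "w", tol=1e-8)
    assert f0w.S_rr == pytest.approx(fsw.S_rr, abs=1e-3)
    for tag in ("rin", "rout", "rc-", "rc+"):
        assert f0w.W[tag] == pytest.approx(fsw.W[tag], abs=1e-4)


def test_stress_traces_stable_under_tolerance_halving(coeffs_ref):
    a = solve_fundamental_bvp(coeffs_ref, 3.0, "u", tol=1e-8)
    b = solve_fundamental_bvp(coeffs_ref, 3.0, "u", tol=5e-9)
    assert abs(a.S_rr - b.S_rr) < 1e-6 * max(1, abs(a.S_rr))
    assert abs(a.S_rz - b.S_rz) < 1e-6 * max(1, abs(a.S_rz))


def test_wall_displacements_decay_in_k(coeffs_ref):
    """The tear field localises: wall amplitudes fall faster than 1/k."""
    ks = [2.0, 4.0, 8.0]
    vals = []
    prev = None
    for k in ks:
        prev = solve_fundamental_bvp(coeffs_ref, k, "u", init=prev)
        vals.append(abs(prev.U["rin"]))
    assert vals[2] < vals[1] < vals[0]
    # faster than 1/k between k=4 and k=8
    assert vals[2] / vals[1] < ks[1] / ks[2]


def test_traction_kernels_grow_linearly_at_large_k(coeffs_ref):
    """S_rr^u ~ c1 k + c0 (the Cauchy/indicator tail of the crack kernel),
    with negative c1: a positive ring opening relieves normal stress."""
    prev = None
    vals = {}
    for k in (8.0, 9.0, 10.0):
        prev = solve_fundamental_bvp(coeffs_ref, k, "u", init=prev)
        vals[k] = prev.S_rr
    s1 = vals[9.0] - vals[8.0]
    s2 = vals[10.0] - vals[9.0]
    assert s1 < 0 and s2 < 0
    assert s2 == pytest.approx(s1, rel=2e-2)


def test_isotropic_limit_reduces_to_incompressible_stokes_system():
    """With k1 -> 0 about an unstressed state the transformed system must
    match the hand-derived axisymmetric incompressible (Stokes-type)
    equations:  c (U'' + U'/r - U/r^2 - k^2 U) + qd' = 0  and the
    third-order eliminated axial equation."""
    p = MaterialParams(c=3.0, k1=1e-15, k2=1.0, beta=0.5)
    g = TubeGeometry(r_in=4.0, r_out=6.0, r_c=5.0, R_in=4.0, kappa=1.0, lam=1.0)
    base = solve_radial_equilibrium(g, p)
    co = derive_coefficient_functions(base)
    c = p.c
    for (r, k) in [(4.3, 0.8), (5.6, 2.4)]:
        cf = co.all_coeffs(np.asarray(r), k)
        # radial equation, normalised by the qd' coefficient
        assert cf["A2"] / cf["D2"] == pytest.approx(-c * (1 / r**2 + k**2), rel=1e-10)
        assert cf["B2"] / cf["D2"] == pytest.approx(c / r, rel=1e-10)
        assert cf["C2"] / cf["D2"] == pytest.approx(c, rel=1e-10)
        # eliminated axial equation, normalised by the U''' coefficient
        assert cf["C1"] / cf["D1"] == pytest.approx(2 / r, rel=1e-10)
        assert cf["B1"] / cf["D1"] == pytest.approx(-(1 / r**2 + k**2), rel=1e-10)
        assert cf["A1"] / cf["D1"] == pytest.approx(1 / r**3 - k**2 / r, rel=1e-10)
        assert cf["E1"] / cf["D1"] == pytest.approx(k**2 / c, rel=1e-10)


def test_manufactured_field_satisfies_assembled_ode(coeffs_ref, base_ref):
    """Method of manufactured solutions: substitute a smooth separable
    field into the assembled ODE and into the incremental PDE evaluated
    through the constitutive layer; the residuals must agree."""
    from ringtear.material import incremental_moduli, incremental_nominal_stress
    from ringtear.base_state import deformation_gradient

    k = 1.3
    g = base_ref.geom
    poly = np.polynomial.Polynomial([0.2, -0.1, 0.05, 0.3])
    qpoly = np.polynomial.Polynomial([0.1, 0.4, -0.2])

    def residual_from_coeffs(r):
        cf = coeffs_ref.all_coeffs(np.asarray(r), k)
        u0, u1, u2, u3 = (poly.deriv(m)(r) for m in range(4))
        qd0, qd1 = qpoly(r), qpoly.deriv()(r)
        res_z = (cf["A1"] * u0 + cf["B1"] * u1 + cf["C1"] * u2
                 + cf["D1"] * u3 + cf["E1"] * qd0)
        res_r = cf["A2"] * u0 + cf["B2"] * u1 + cf["C2"] * u2 + cf["D2"] * qd1
        return float(res_r), float(res_z)

    def residual_from_pde(r, h=1e-4):
        """div Sdot0 for u = f(r) cos kz, w = -(f'+f/r)/k sin kz at z=0
        and z = pi/(2k), via the material layer and FD in r."""
        def amps(rr):
            u0, u1, u2 = poly(rr), poly.deriv()(rr), poly.deriv(2)(rr)
            w0 = -(u1 + u0 / rr) / k
            w1 = -(u2 + u1 / rr - u0 / rr**2) / k
            A = deformation_gradient(g, rr)
            mod = incremental_moduli(base_ref.params, A)
            qv = float(base_ref.q_at(rr))
            qd0 = qpoly(rr)
            # same-trig components (cos): S_rr, S_tt, S_zz
            dA_cos = np.array([[u1, 0, 0], [0, u0 / rr, 0], [0, 0, k * w0]])
            S_cos = incremental_nominal_stress(mod, qv, qd0, dA_cos)
            # other-trig components (sin): S_rz, S_zr from u_z, w_r
            dA_sin = np.array([[0, 0, -k * u0], [0, 0, 0], [w1, 0, 0]])
            S_sin = np.einsum("ijkl,lk->ij", mod, dA_sin) - qv * dA_sin
            return S_cos, S_sin

        Sc, Ss = amps(r)
        Scp, Ssp = amps(r + h)
        Scm, Ssm = amps(r - h)
        dSrr = (Scp[0, 0] - Scm[0, 0]) / (2 * h)
        dSrz = (Ssp[0, 2] - Ssm[0, 2]) / (2 * h)
        res_r = dSrr + (Sc[0, 0] - Sc[1, 1]) / r + k * Ss[2, 0]
        res_z = dSrz + Ss[0, 2] / r - k * Sc[2, 2]
        return float(res_r), float(res_z)

    for r in (4.4, 5.5):
        res_r_c, res_z_c = residual_from_coeffs(r)
        res_r_p, res_z_p = residual_from_pde(r)
        assert res_r_c == pytest.approx(res_r_p, rel=1e-6, abs=1e-6)
        assert res_z_c == pytest.approx(res_z_p, rel=1e-6, abs=1e-6)


def test_rejects_bad_inputs(coeffs_ref):
    with pytest.raises(ValueError):
        solve_fundamental_bvp(coeffs_ref, -1.0, "u")
    with pytest.raises(ValueError):
        solve_fundamental_bvp(coeffs_ref, 1.0, "x")
    with pytest.raises(ValueError):
        k_zero_solve(coeffs_ref, "x")
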