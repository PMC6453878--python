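"""Computer-algebra backbone of the package.

Everything that the tear model needs from the constitutive law is derived
here symbolically, once per process, and compiled to vectorised numpy
callables:

* the HGO strain energy, its gradient (nominal stress) and Hessian
  (referential elastic moduli) with respect to a general deformation
  gradient;
* the push-forward incremental moduli evaluated on the diagonal base
  deformation of the closed, axially stretched tube;
* the coefficient functions of the Fourier-transformed incremental
  equilibrium ODE system (the third-order equation in the transformed
  radial displacement plus the first-order equation for the transformed
  pressure increment), including the stress-reconstruction coefficients
  used for boundary, jump and trace evaluations;
* closed-form base-state stress profiles along the tube wall.

Finite differences are used only as an independent test oracle; the model
itself never differentiates numerically.
"""

from __future__ import annotations

from functools import lru_cache

import sympy as sp

# material parameters: matrix stiffness c, fibre stiffness k1, fibre
# exponent k2, fibre angle beta (from the circumferential direction)
_C, _K1, _K2, _BETA = sp.symbols("c k1 k2 beta", positive=True)
# deformation / geometry parameters of the closed tube
_KAPPA, _LAM, _RIN, _RREF = sp.symbols("kappa lam rin Rin", positive=True)

#: argument order of all lambdified parameterised callables
PARAM_ARGS = ("c", "k1", "k2", "beta", "kappa", "lam", "rin", "Rin")

_IDX = "rtz"  # index 0=r, 1=theta, 2=z


def hgo_energy(A: sp.Matrix, c, k1, k2, beta):
    """HGO strain energy for deformation gradient ``A`` (symbolic).

    Isotropic neo-Hookean matrix plus two exponentially stiffening
    collagen-fibre families at +/-beta in the (theta, z) plane.
    """
    C = A.T * A
    I1 = sp.trace(C)
    cb, sb = sp.cos(beta), sp.sin(beta)
    Mp = sp.Matrix([[0, 0, 0], [0, cb**2, cb * sb], [0, cb * sb, sb**2]])
    Mm = sp.Matrix([[0, 0, 0], [0, cb**2, -cb * sb], [0, -cb * sb, sb**2]])
    I4 = sp.trace(Mp * C)
    I6 = sp.trace(Mm * C)

    def psi_f(x):
        return sp.exp(k2 * (x - 1) ** 2) - 1

    return c / 2 * (I1 - 3) + k1 / (2 * k2) * (psi_f(I4) + psi_f(I6))


@lru_cache(maxsize=None)
def _generic_energy():
    """Energy and gradient w.r.t. a fully general 3x3 deformation gradient."""
    A = sp.Matrix(3, 3, lambda i, j: sp.Symbol(f"A_{i}{j}"))
    W = hgo_energy(A, _C, _K1, _K2, _BETA)
    dW = sp.Matrix(3, 3, lambda i, j: sp.diff(W, A[i, j]))
    return A, W, dW


@lru_cache(maxsize=None)
def energy_callables():
    """Callables ``W(A9..., c, k1, k2, beta)`` and ``dWdA`` (3x3)."""
    A, W, dW = _generic_energy()
    args = list(A) + [_C, _K1, _K2, _BETA]
    fW = sp.lambdify(args, W, modules="numpy", cse=True)
    fdW = sp.lambdify(args, dW, modules="numpy", cse=True)
    return fW, fdW


@lru_cache(maxsize=None)
def _hessian_diag():
    """d2W/dA_jalpha dA_lbeta evaluated at A = diag(ar, at, az).

    Returns a dict keyed by the 4-tuple (j, alpha, l, beta) of matrix
    indices (0=r, 1=theta, 2=z) -> sympy expression in ar, at, az and
    the material parameters.
    """
    A, W, dW = _generic_energy()
    ar, at, az = sp.symbols("ar at az", positive=True)
    diag_sub = {A[i, j]: 0 for i in range(3) for j in range(3) if i != j}
    diag_sub.update({A[0, 0]: ar, A[1, 1]: at, A[2, 2]: az})
    H = {}
    for m in range(3):
        for n in range(3):
            for p in range(3):
                for s in range(3):
                    if (p, s, m, n) in H:
                        H[(m, n, p, s)] = H[(p, s, m, n)]
                        continue
                    H[(m, n, p, s)] = sp.diff(dW[m, n], A[p, s]).subs(diag_sub)
    return (ar, at, az), H


def _moduli_component(i, j, k, l, a_syms=None, H=None):
    """Push-forward incremental modulus A0_{ijkl} at diagonal A (symbolic).

    A0_{ijkl} = A_{i alpha} A_{k beta} d2W/dA_{j alpha} dA_{l beta}; on a
    diagonal gradient alpha=i and beta=k survive.
    """
    if H is None:
        a_syms, H = _hessian_diag()
    a = a_syms
    return a[i] * a[k] * H[(j, i, l, k)]


@lru_cache(maxsize=None)
def moduli_diag_callable():
    """Full (3,3,3,3) push-forward moduli at diagonal A.

    Returns ``f(ar, at, az, c, k1, k2, beta) -> nested 3x3x3x3 list``.
    """
    a_syms, H = _hessian_diag()
    comps = [
        _moduli_component(i, j, k, l, a_syms, H)
        for i in range(3)
        for j in range(3)
        for k in range(3)
        for l in range(3)
    ]
    args = list(a_syms) + [_C, _K1, _K2, _BETA]
    return sp.lambdify(args, comps, modules="numpy", cse=True)


# ---------------------------------------------------------------------------
# base-state closed forms
# ---------------------------------------------------------------------------


def _base_stretches(r):
    """Principal stretches of the closed tube as closed-form functions of r."""
    R = sp.sqrt(_KAPPA * _LAM * (r**2 - _RIN**2) + _RREF**2)
    ar = R / (_KAPPA * _LAM * r)
    at = _KAPPA * r / R
    az = _LAM
    return ar, at, az


@lru_cache(maxsize=None)
def base_profile_callables():
    """Closed-form base-state stress profiles along the wall.

    Returns callables of ``(r, c, k1, k2, beta, kappa, lam, rin, Rin)``:

    ``sig_diff``    sigma_tt - sigma_rr (the q-free radial-equilibrium
                    integrand numerator),
    ``sig_rr_el``   a_r dW/da_r, the elastic part of the radial Cauchy
                    stress (sigma_rr = sig_rr_el + q),
    ``dsig_rr_el``  its exact r-derivative.
    """
    r = sp.Symbol("r", positive=True)
    ar_e, at_e, az_e = _base_stretches(r)
    a_syms, _ = _hessian_diag()
    A, W, dW = _generic_energy()
    diag_sub = {A[i, j]: 0 for i in range(3) for j in range(3) if i != j}
    diag_sub.update({A[0, 0]: a_syms[0], A[1, 1]: a_syms[1], A[2, 2]: a_syms[2]})
    Wr = dW[0, 0].subs(diag_sub)
    Wt = dW[1, 1].subs(diag_sub)
    base_sub = {a_syms[0]: ar_e, a_syms[1]: at_e, a_syms[2]: az_e}
    Wz = dW[2, 2].subs(diag_sub)
    sig_rr_el = (a_syms[0] * Wr).subs(base_sub)
    sig_tt_el = (a_syms[1] * Wt).subs(base_sub)
    sig_zz_el = (a_syms[2] * Wz).subs(base_sub)
    sig_diff = sig_tt_el - sig_rr_el
    dsig_rr_el = sp.diff(sig_rr_el, r)
    args = [r, _C, _K1, _K2, _BETA, _KAPPA, _LAM, _RIN, _RREF]
    return {
        "sig_diff": sp.lambdify(args, sig_diff, modules="numpy", cse=True),
        "sig_rr_el": sp.lambdify(args, sig_rr_el, modules="numpy", cse=True),
        "sig_zz_el": sp.lambdify(args, sig_zz_el, modules="numpy", cse=True),
        "dsig_rr_el": sp.lambdify(args, dsig_rr_el, modules="numpy", cse=True),
    }


# ---------------------------------------------------------------------------
# Fourier-transformed incremental equilibrium ODE system
# ---------------------------------------------------------------------------

#: names of the ODE / stress-reconstruction coefficient functions, in the
#: order returned by :func:`ode_coefficient_callable`
ODE_COEFF_NAMES = (
    "A1", "B1", "C1", "D1", "E1",      # z-equilibrium: A1 U + B1 U' + C1 U'' + D1 U''' + E1 qd = 0
    "A2", "B2", "C2", "D2",            # r-equilibrium: A2 U + B2 U' + C2 U'' + D2 qd' = 0
    "sr1", "sr2",                      # S_rr = sr1 U + sr2 U' + qd
    "sz1", "sz2", "sz3",               # S_rz = sz1 U + sz2 U' + sz3 U''
)


@lru_cache(maxsize=None)
def _ode_coefficient_exprs():
    """Derive the transformed ODE coefficients.

    A separable incremental field is substituted into the incremental
    equilibrium equations written on the deformed tube: for a radial-jump
    fundamental problem u = U(r) cos kz, w = W(r) sin kz and for an
    axial-jump problem u = U(r) sin kz, w = W(r) cos kz.  The axial
    amplitude is eliminated through incompressibility,
    W = -eps (U' + U/r)/k with eps = +1 (radial jump) or -1 (axial jump);
    the parity sign eps then factors out of every equation, so a single
    real coefficient set serves both fundamental problems.

    The hydrostatic pressure q(r) of the base state and its derivative
    appear as the free symbols ``qv`` and ``qp``.
    """
    r, k = sp.symbols("r k", positive=True)
    qv, qp = sp.symbols("qv qp", real=True)

    # opaque moduli components: keeps the collection step small; the full
    # closed-form r-dependence is substituted afterwards
    names = {}
    need = [
        (0, 0, 0, 0), (0, 0, 1, 1), (0, 0, 2, 2),
        (1, 1, 0, 0), (1, 1, 1, 1), (1, 1, 2, 2),
        (2, 2, 0, 0), (2, 2, 1, 1), (2, 2, 2, 2),
        (0, 2, 2, 0), (0, 2, 0, 2), (2, 0, 2, 0), (2, 0, 0, 2),
    ]
    for idx in need:
        tag = "".join(_IDX[x] for x in idx)
        names[idx] = sp.Function(f"M{tag}")(r)

    def M(i, j, kk, l):
        return names[(i, j, kk, l)]

    U = sp.Function("U")(r)
    Qd = sp.Function("Qd")(r)
    qfun = sp.Function("qbase")(r)
    Up = U.diff(r)

    wamp = -(Up + U / r) / k          # axial amplitude per unit eps
    wz = -(Up + U / r)                # w_z amplitude (eps-free)
    wp = wamp.diff(r)

    Srr = (M(0, 0, 0, 0) - qfun) * Up + M(0, 0, 1, 1) * U / r + M(0, 0, 2, 2) * wz + Qd
    Stt = M(1, 1, 0, 0) * Up + (M(1, 1, 1, 1) - qfun) * U / r + M(1, 1, 2, 2) * wz + Qd
    Szz = M(2, 2, 0, 0) * Up + M(2, 2, 1, 1) * U / r + (M(2, 2, 2, 2) - qfun) * wz + Qd
    # shear amplitudes per unit eps (u_z amplitude is -eps k U, w_r is eps W')
    Srz = -k * (M(0, 2, 2, 0) - qfun) * U + M(0, 2, 0, 2) * wp
    Szr = -k * M(2, 0, 2, 0) * U + (M(2, 0, 0, 2) - qfun) * wp

    zeq = sp.expand(Srz.diff(r) + Srz / r - k * Szz)
    req = sp.expand(Srr.diff(r) + (Srr - Stt) / r + k * Szr)

    # flatten derivatives to plain symbols for coefficient extraction
    u0, u1, u2, u3 = sp.symbols("u0 u1 u2 u3")
    qd0, qd1 = sp.symbols("qd0 qd1")
    flat = {
        U.diff(r, 3): u3, U.diff(r, 2): u2, U.diff(r): u1, U: u0,
        Qd.diff(r): qd1, Qd: qd0,
        qfun.diff(r): qp, qfun: qv,
    }
    # opaque moduli derivatives -> symbols
    msyms, dmsyms, m_exprs = {}, {}, {}
    for idx, f in names.items():
        tag = str(f.func)
        msyms[idx] = sp.Symbol(tag)
        dmsyms[idx] = sp.Symbol("d" + tag)
        flat[f.diff(r)] = dmsyms[idx]
        flat[f] = msyms[idx]

    def extract(expr, var):
        return sp.expand(expr).coeff(var)

    zeq = zeq.subs(flat)
    req = req.subs(flat)
    Srr_f = Srr.subs(flat)
    Srz_f = Srz.subs(flat)

    coeffs = {
        "A1": extract(zeq, u0), "B1": extract(zeq, u1),
        "C1": extract(zeq, u2), "D1": extract(zeq, u3), "E1": extract(zeq, qd0),
        "A2": extract(req, u0), "B2": extract(req, u1),
        "C2": extract(req, u2), "D2": extract(req, qd1),
        "sr1": extract(Srr_f, u0), "sr2": extract(Srr_f, u1),
        "sz1": extract(Srz_f, u0), "sz2": extract(Srz_f, u1), "sz3": extract(Srz_f, u2),
    }
    # sanity: linear structure must be exact
    check = sp.expand(
        zeq - coeffs["A1"] * u0 - coeffs["B1"] * u1 - coeffs["C1"] * u2
        - coeffs["D1"] * u3 - coeffs["E1"] * qd0
    )
    if sp.simplify(check) != 0:
        raise RuntimeError("z-equilibrium collection failed")  # pragma: no cover
    check = sp.expand(req - coeffs["A2"] * u0 - coeffs["B2"] * u1
                      - coeffs["C2"] * u2 - coeffs["D2"] * qd1)
    if sp.simplify(check) != 0:
        raise RuntimeError("r-equilibrium collection failed")  # pragma: no cover

    # substitute the closed-form base-state r-dependence of the moduli
    a_syms, H = _hessian_diag()
    ar_e, at_e, az_e = _base_stretches(r)
    base_sub = {a_syms[0]: ar_e, a_syms[1]: at_e, a_syms[2]: az_e}
    mod_sub = {}
    for idx in need:
        comp = _moduli_component(*idx, a_syms, H).subs(base_sub)
        mod_sub[msyms[idx]] = comp
        mod_sub[dmsyms[idx]] = sp.diff(comp, r)
    coeffs = {nm: e.subs(mod_sub) for nm, e in coeffs.items()}
    return (r, k, qv, qp), coeffs


#: coefficient functions that stay finite in the k -> 0 limit
K0_COEFF_NAMES = ("A2", "B2", "C2", "D2", "sr1", "sr2")


@lru_cache(maxsize=None)
def ode_coefficient_k0_callable():
    """Radial-equilibrium and S_rr coefficients at exactly k = 0.

    The axial equation degenerates at k = 0 (the incompressibility
    elimination is singular there); the radial equation and the normal
    stress reconstruction stay regular and are lambdified with k
    substituted symbolically.
    """
    (r, k, qv, qp), coeffs = _ode_coefficient_exprs()
    exprs = [sp.cancel(coeffs[nm]).subs(k, 0) for nm in K0_COEFF_NAMES]
    args = [r, qv, qp, _C, _K1, _K2, _BETA, _KAPPA, _LAM, _RIN, _RREF]
    return sp.lambdify(args, exprs, modules="numpy", cse=True)


@lru_cache(maxsize=None)
def ode_coefficient_callable():
    """Vectorised evaluator of all transformed-ODE coefficient functions.

    Returns ``f(r, k, qv, qp, c, k1, k2, beta, kappa, lam, rin, Rin)`` ->
    list of arrays ordered as :data:`ODE_COEFF_NAMES`.  ``qv``/``qp`` are
    the base-state Lagrange pressure q(r) and its derivative.
    """
    (r, k, qv, qp), coeffs = _ode_coefficient_exprs()
    exprs = [coeffs[nm] for nm in ODE_COEFF_NAMES]
    args = [r, k, qv, qp, _C, _K1, _K2, _BETA, _KAPPA, _LAM, _RIN, _RREF]
    return sp.lambdify(args, exprs, modules="numpy", cse=True)
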