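# Methods

## Scope and assumptions

The package models a *static*, axisymmetric dissection in the media of
a large artery.  The wall is a single incompressible hyperelastic layer
(HGO energy: neo-Hookean matrix `c` plus two exponential collagen
families at ±β from the circumferential direction).  Residual stress
enters through the opening angle α of the cut-open, stress-free
configuration (κ = 2π/(2π−α) ≥ 1) and the in-vivo axial pre-stretch λ.
The tear is a slit of half-length L on the cylinder r = r_c, flooded by
lumen fluid at the (static) lumen pressure; tear propagation, cohesive
zones, two-layer walls, inner-wall buckling and blood flow are outside
the model.  The dissection itself is treated as an *incremental*
(linearised) deformation superposed on the finite base state, so all
computed openings are first-order in the driving traction.

## Base state

Given (r_in, r_out, r_c, R_in, κ, λ), incompressibility fixes the
reference map `R(r) = sqrt(κλ(r²−r_in²)+R_in²)` and the principal
stretches a_r = R/(κλr), a_θ = κr/R, a_z = λ; R_out is derived, so the
*current* geometry is what the user prescribes.  The single radial
equilibrium equation dσ_rr/dr = (σ_θθ−σ_rr)/r is integrated inward from
σ_rr(r_out) = −P_ext.  Because the integrand σ_θθ−σ_rr is free of the
Lagrange pressure it has a closed symbolic form; σ_rr is a single
cumulative Simpson quadrature on a 2001-point grid (refinement-checked
to 1e-8 kPa), q(r) = σ_rr − a_r ∂Ψ/∂a_r follows algebraically, and
P_in = −σ_rr(r_in) is the lumen pressure that maintains the
configuration.  q′(r) is assembled exactly from equilibrium plus the
closed-form derivative of the elastic part — no numerical
differentiation anywhere in the model path.

## Constitutive derivatives by computer algebra

The incremental constitutive response needs second derivatives of the
energy.  These are derived once per process with sympy from the energy
written in a fully general 3×3 deformation gradient, evaluated on the
diagonal base state, pushed forward
(`A0_ijkl = A_iα A_kβ ∂²Ψ/∂A_jα∂A_lβ`), and compiled to vectorised
numpy callables (with common-subexpression elimination).  The same
pipeline substitutes the separable incremental ansatz
(u = U(r)·{cos,sin}kz, w = W(r)·{sin,cos}kz) into the incremental
equilibrium equations, eliminates W through incompressibility
(W = −ε(U′+U/r)/k, ε = ±1 for the radial/axial jump problem), and
collects the coefficient functions of the resulting ODE system

    A1 U + B1 U′ + C1 U″ + D1 U‴ + E1 q̇ = 0      (axial equilibrium)
    A2 U + B2 U′ + C2 U″ + D2 q̇′       = 0      (radial equilibrium)

together with the stress-reconstruction rows
S_rr = s_r1 U + s_r2 U′ + q̇ and S_rz = s_z1 U + s_z2 U′ + s_z3 U″.
The parity sign ε cancels identically, so one real coefficient set
serves both fundamental problems.  Validation: the coefficients reduce
exactly to the hand-derived incompressible Stokes-type system in the
fibre-free unstressed limit, and a manufactured separable field gives
identical residuals through the ODE coefficients and through the
(independent) moduli-contraction path; the moduli themselves match
central finite differences of the nominal stress to 1e-6.

## Fundamental jump solutions

For each wavenumber k the two-region BVP (region 1: [r_in, r_c], region
2: [r_c, r_out], both mapped to t ∈ [0,1] with the tear face at t = 1)
is solved as one 8-dimensional first-order system with
`scipy.integrate.solve_bvp` (analytic Jacobians, continuation in k
along the quadrature grid).  Boundary conditions at the walls are the
incremental traction conditions S_rr = P u′, S_rz = P u_z with
P = P_in / P_ext; at the tear the four imposed conditions are the
prescribed jumps [U], [U′] (equivalent to the unit displacement jump
and continuity of the other displacement component) and traction
continuity [S_rr] = [S_rz] = 0.  A fifth continuity condition on the
pressure increment is *not* imposable — with the four physical
conditions the 8-constant problem is closed and [q̇] is then determined
(and generally nonzero); it is reported on the solution object as a
diagnostic.  The default collocation tolerance is 1e-6
(config-exposed): stress traces agree with tol = 1e-8 runs to eight
decimals, and the jump/boundary conditions are imposed exactly through
the boundary-condition rows at any tolerance.

k = 0 is a singular limit: the axial amplitude carries a rigid/flux
mode (for the radial jump W ~ V0/k with spatially uniform V0 that is
fixed only at second order in k).  The k = 0 column of the quadrature
is therefore obtained by k²-Richardson extrapolation of two small-k
solves (k = 2e-3 and 1e-3), which is continuous with the k→0⁺ family
to ~1e-6; the 1/k coefficients (lim k·U, lim k·W per surface) are kept
for the k = 0 node of the sine-type kernel integrands, whose limit is
a0·Δ·(z_i−z_j).

## Influence matrices

The opening is piecewise constant on 2N elements of half-width
Δ = L/(2N) centred at z_j = −L+(2j−1)Δ.  Each transformed kernel
sampled on the uniform grid k_m = m·k_max/N_k is split as
raw(k) ≈ c1·k + c0 + tilde(k), the coefficients fitted by least squares
on the top 20% of the grid (displacement kernels: constant-only, as
their transforms tend to constants).  The decaying part is integrated
by composite trapezoid with sin(kΔ)/k kept in the integrand; the
closed-form inverse transforms of the singular parts are the
Cauchy term −c1·2Δ/(π((z_i−z_j)²−Δ²)) and the indicator c0·1(i=j) for
cosine-type kernels, and (c0/π)·log|(z_i−z_j+Δ)/(z_i−z_j−Δ)| for
sine-type kernels (the linear sine part integrates to zero on the
even-multiple-of-Δ lattice).  All collocation points and evaluation
stations live on that lattice — misuse raises a configuration error —
and every block is Toeplitz in z_i−z_j, so assembly costs O(N) kernel
evaluations per block.  Displacement stations cover
|z| ≤ station_extent·L (default 3, i.e. 120 stations for 2N = 40);
tying the station count to the lattice replaces a free station-count
knob.

Normalisation: fundamental solutions carry a unit *transformed* jump,
paired with the inversion f(z) = (1/π)∫₀^∞ f̂ {cos,sin}(kz) dk.  Under
this pairing the solved density U_j *is* the local normal opening of
the faces, and the maximum dissection width is max_j U_j (verified to
coincide with the face-difference of the kernel-evaluated profiles to
1e-10).  Any common rescaling of the fundamental solutions cancels
between the traction and displacement matrices.

## Tractions, signs, and the pressure increment

Connecting the tear to the lumen loads the faces with
T_r = σ_rr(r_in) − σ_rr(r_c) − Ṗ, T_z = 0.  In an inflated artery
|σ_rr| decreases outward, so T_r < 0; in this sign convention a
*negative* T_r is the face-opening (fluid-pressure) load, exactly as a
pressurised crack carries S_rr = −p on its faces, and the solved
opening is then positive.

A pressure increment Ṗ on lumen and faces adds a z-independent, purely
radial field.  Incompressibility forces u = C/r across the whole wall;
q̇ follows by quadrature of the k = 0 radial-equilibrium coefficients,
and the two constants are fixed by the inner (with +Ṗ) and outer
incremental traction conditions.  Its face stress S_rr^P(r_c)·Ṗ moves
to the right-hand side of the density system and u^P·Ṗ adds to every
surface profile.  In the fibre-free unstressed limit this field reduces
to the classical incompressible Lamé solution
C = Ṗ/(2c(1/r_in²−1/r_out²)) (matched to 1e-8) and to the thin-shell
estimate Ṗr²/(4ct) within 10%.

## Independent oracles

*Axisymmetric mixed FEM.*  Q2 displacement / Q1 pressure (Taylor–Hood)
on a structured mesh of the tube cross-section, with the slit realised
by duplicating displacement *and* pressure nodes strictly inside the
tear (tips shared).  The weak form uses the incremental moduli, the
base-state q(r), and — about pre-stressed base states — the
follower-pressure boundary stiffness from the wall conditions.  End
sections default to rollers (u_z = 0, radially free): this emulates the
infinite tube held at fixed axial stretch, and is essential — with free
ends the tube develops uniform axial strain under lumen pressure and
the slit-free response deviates ~35% from the exact u = C/r field,
while roller ends reproduce it to 5e-5.  A traction-free-ends variant
is retained.  The finite-tube benchmark (16 mm tube, 4 mm tear,
0.1 kPa) agrees with the wavenumber-domain solver to a stable ≈3.3%
(mesh-converged FEM 0.1595 mm vs Green's 0.1542 mm), the residual being
the finite length and the displacement-discontinuity idealisation.

*Direct-domain cross-check about general base states* uses the same FEM
machinery with the tear faces loaded by ±T_r, agreeing with the
pipeline within 5% at modest meshes.

*Per-wavenumber FD oracle* (tests): a trapezoidal box scheme on a fine
fixed mesh, an entirely different discretisation of the same ODE,
agreeing to 1e-5.

*Synthetic-kernel oracle*: influence entries for kernels
c1·k + c0 + a·e^{−bk} have elementary closed forms (arctan/log); the
assembly path matches them to better than 1e-3, and the singular
closed forms match mpmath oscillatory quadrature of their generating
integrals.

## Parameters and defaults

| parameter | default | units | provenance |
|---|---|---|---|
| c | 3.0 | kPa | rabbit carotid media fit |
| k1 | 2.3632 | kPa | rabbit carotid media fit |
| k2 | 0.8393 | – | rabbit carotid media fit |
| β | π/3 | rad | reference configuration |
| r_in, r_c, r_out | 4, 5, 6 | mm | reference geometry |
| R_in | 3.9 | mm | reference geometry |
| λ | 1.1 | – | package default (typical in-vivo pre-stretch); "assumed" warning logged |
| L | 2.0 | mm | package default, matches the validation tear length |
| 2N | 40 | – | package choice; width changes <0.1% vs 2N = 80 |
| k_max, N_k | 10, 300 | 1/mm, – | production quadrature; within 0.1% of (30, 1500) |
| bvp_tol | 1e-6 | – | collocation tolerance (see above) |

Lumen-radius trend: "decreasing r_in" is parameterised at fixed
circumferential pre-strain ratio R_in/r_in (smaller lumen, same
inflation).  Holding R_in fixed instead flips the inner wall into
circumferential compression and is a different physical experiment; the
distinction matters for the sign of the trend and is the reason the
parameterisation is documented here.

## Numerical sizes used by the test suite

Unit tests run coarse quadrature (k_max = 6, N_k = 60, 2N = 20); the
end-to-end verification tests use the production setting
(k_max = 10, N_k = 300, 2N = 40) and the refined (30, 1500) control,
with FEM meshes up to 96×24 Q2 elements.  Fundamental-solution sweeps
are cached per base state and quadrature setting within a process.

## Known limitations

* The incremental (linear) treatment cannot describe contact of the
  faces under compressive loads (a negative opening is reported as-is)
  nor large openings; widths scale exactly linearly with the driving
  traction by construction.
* The k = 0 extrapolation and the 1/k tails of the tear-face
  displacement kernels limit face-profile accuracy to ~1e-3 relative;
  the opening itself is exact in the density representation.
* Only axisymmetric tears and a single-layer wall are modelled; the
  fibre families are symmetric and mechanically equivalent
  (I4 = I6 on every axisymmetric state).
* The FEM oracle linearises about the same base states as the model;
  it is an independent discretisation, not an independent constitutive
  implementation (the moduli generator is shared, but is itself
  finite-difference-validated).
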