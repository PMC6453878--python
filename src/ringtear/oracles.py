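"""Independent validation solvers.

These never feed the production pipeline; they exist to cross-check it.

* :func:`fem_finite_tube` — axisymmetric mixed finite-element solution
  (Q2 displacement / Q1 pressure, Taylor-Hood) of the incremental
  equations on a finite tube with a slit at the tear radius, loaded by a
  small pressure on the lumen and tear faces.  Reproduces the
  finite-tube benchmark used to validate the wavenumber-domain solver.
* :func:`fd_direct_solver` — the same direct-domain discretisation about
  a general (residually stressed, pre-stretched) base state, including
  the follower-pressure boundary stiffness, with the tear faces loaded
  by the incremental tear traction.
* :func:`isotropic_limit_check` — structural check of the fibre-free
  limit: the far field of a compact dissection decays algebraically
  along the wall, as for a ring dislocation in an isotropic solid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps
from scipy.sparse.linalg import spsolve

from .base_state import BaseState, TubeGeometry, solve_radial_equilibrium
from .material import DeformationGradientDiag, MaterialParams, incremental_moduli

__all__ = ["OracleReport", "AxisymmetricFEM", "fem_finite_tube",
           "fd_direct_solver", "isotropic_limit_check"]


@dataclass
class OracleReport:
    """Comparison record between the production solver and an oracle."""

    quantity: str
    solver_value: float
    oracle_value: float
    metadata: dict = field(default_factory=dict)

    @property
    def rel_diff(self) -> float:
        a, b = self.solver_value, self.oracle_value
        return abs(a - b) / max(abs(a), abs(b), 1e-300)


# ---------------------------------------------------------------------------
# Q2/Q1 axisymmetric mixed FEM on a structured rectangle mesh with a slit
# ---------------------------------------------------------------------------

_GAUSS3 = np.array([-np.sqrt(3 / 5), 0.0, np.sqrt(3 / 5)])
_W3 = np.array([5 / 9, 8 / 9, 5 / 9])


def _q2_shape(xi, eta):
    """9-node biquadratic shape functions and parent derivatives."""
    def l(x):
        return np.array([0.5 * x * (x - 1), 1 - x * x, 0.5 * x * (x + 1)])

    def dl(x):
        return np.array([x - 0.5, -2 * x, x + 0.5])

    N = np.outer(l(xi), l(eta)).ravel()
    dNx = np.outer(dl(xi), l(eta)).ravel()
    dNe = np.outer(l(xi), dl(eta)).ravel()
    return N, dNx, dNe


def _q1_shape(xi, eta):
    l = lambda x: np.array([0.5 * (1 - x), 0.5 * (1 + x)])
    return np.outer(l(xi), l(eta)).ravel()


class AxisymmetricFEM:
    """Incremental axisymmetric elasticity on a tube cross-section.

    Structured quadrilateral mesh on (z, r) in [-Lz/2, Lz/2] x
    [r_in, r_out]; a slit of half-length L_tear along r = r_c is realised
    by duplicating the nodes strictly inside the slit (crack tips stay
    shared), cutting displacement and pressure fields alike.
    """

    def __init__(self, r_in, r_out, r_c, Lz, L_tear, nz, nr):
        self.r_in, self.r_out, self.r_c = r_in, r_out, r_c
        self.Lz, self.L_tear = Lz, L_tear
        self.nz, self.nr = nz, nr
        self.dz, self.dr = Lz / nz, (r_out - r_in) / nr
        # the slit must run along mesh lines with tips on corner nodes
        i_c = (r_c - r_in) / self.dr
        j_t = L_tear / self.dz
        if abs(i_c - round(i_c)) > 1e-9 or abs(j_t - round(j_t)) > 1e-9:
            raise ValueError("mesh must align with the tear radius and tips")
        self._build_mesh()

    # -- mesh ------------------------------------------------------------
    def _build_mesh(self):
        nz, nr = self.nz, self.nr
        nzf, nrf = 2 * nz + 1, 2 * nr + 1
        zf = -self.Lz / 2 + np.arange(nzf) * self.dz / 2
        rf = self.r_in + np.arange(nrf) * self.dr / 2

        def base_id(i, j):          # i: r index (fine), j: z index (fine)
            return i * nzf + j

        n_base = nrf * nzf
        i_slit = int(round((self.r_c - self.r_in) / (self.dr / 2)))
        on_slit = np.zeros((nrf, nzf), dtype=bool)
        on_slit[i_slit, np.abs(zf) < self.L_tear - 1e-12] = True
        # duplicate slit nodes for the upper (r > r_c) side
        dup_ids = {}
        nid = n_base
        for j in np.nonzero(on_slit[i_slit])[0]:
            dup_ids[(i_slit, j)] = nid
            nid += 1
        self.n_nodes = nid
        coords = np.zeros((self.n_nodes, 2))
        I, J = np.meshgrid(np.arange(nrf), np.arange(nzf), indexing="ij")
        coords[: n_base, 0] = zf[J.ravel()]
        coords[: n_base, 1] = rf[I.ravel()]
        for (i, j), d in dup_ids.items():
            coords[d] = (zf[j], rf[i])
        self.coords = coords

        # element connectivity (9 fine nodes each); elements in row er use
        # duplicated ids on their bottom edge if that edge lies on the slit
        # and the element sits above it
        conn = np.zeros((self.nr * nz, 9), dtype=int)
        e = 0
        self.elem_rc = np.zeros(self.nr * nz)
        for er in range(self.nr):
            for ez in range(nz):
                ids = []
                for a in range(3):          # xi-direction: z
                    for b in range(3):      # eta-direction: r
                        i = 2 * er + b
                        j = 2 * ez + a
                        if (i, j) in dup_ids and 2 * er == i:
                            # bottom edge of an element above the slit
                            ids.append(dup_ids[(i, j)])
                        else:
                            ids.append(base_id(i, j))
                conn[e] = ids
                self.elem_rc[e] = rf[2 * er + 1]
                e += 1
        self.conn = conn
        self.i_slit_fine = i_slit
        self.dup_ids = dup_ids
        self.zf, self.rf = zf, rf

        # Q1 pressure nodes: the corner subset of the fine grid (reusing
        # the same ids keeps the bookkeeping simple; duplicated corner
        # nodes on the slit cut the pressure space too)
        self.pconn = conn[:, [0, 2, 6, 8]]
        p_ids = np.unique(self.pconn)
        self.p_index = {g: i for i, g in enumerate(p_ids)}
        self.p_ids = p_ids

    # -- assembly ---------------------------------------------------------
    def assemble(self, moduli_at, q_at, follower=None):
        """Assemble the saddle system.

        ``moduli_at(r) -> (3,3,3,3)`` and ``q_at(r) -> float`` supply the
        base-state fields; ``follower`` is an optional list of
        (edge_nodes, n_r, P) surface-stiffness specifications.
        """
        ndof_u = 2 * self.n_nodes
        ndof_p = self.p_ids.size
        # gradient component order: (u_r,r) (u_r,z) (u_z,r) (u_z,z) (u_r/r)
        comp = [(0, 0), (0, 2), (2, 0), (2, 2), (1, 1)]
        trace_row = np.array([1.0, 0.0, 0.0, 1.0, 1.0])
        swap = np.array([[1, 0, 0, 0, 0], [0, 0, 1, 0, 0], [0, 1, 0, 0, 0],
                         [0, 0, 0, 1, 0], [0, 0, 0, 0, 1.0]])

        # precompute shape data at the 3x3 Gauss points
        pts = [(xi, eta, wx * we) for xi, wx in zip(_GAUSS3, _W3)
               for eta, we in zip(_GAUSS3, _W3)]
        detJ = (self.dz / 2) * (self.dr / 2)

        rows_K, cols_K, vals_K = [], [], []
        rows_B, cols_B, vals_B = [], [], []
        # moduli depend on r only: cache the 5x5 operator per Gauss radius
        Ecache = {}
        for xi, eta, wgt in pts:
            N, dNx, dNe = _q2_shape(xi, eta)
            dNz = dNx * 2 / self.dz
            dNr = dNe * 2 / self.dr
            psi = _q1_shape(xi, eta)
            for e in range(self.conn.shape[0]):
                ids = self.conn[e]
                zc = self.coords[ids[4], 0]
                rc_el = self.coords[ids[4], 1]
                rg = rc_el + eta * self.dr / 2
                key = round(rg, 12)
                if key not in Ecache:
                    A0 = moduli_at(rg)
                    qv = q_at(rg)
                    E = np.empty((5, 5))
                    for a, (ca, da) in enumerate(comp):
                        for b, (cb, db) in enumerate(comp):
                            E[a, b] = A0[da, ca, db, cb]
                    Ecache[key] = E - qv * swap
                Eq = Ecache[key]

                # B: (5 x 18) for dofs [u_r(9), u_z(9)]
                B = np.zeros((5, 18))
                B[0, :9] = dNr
                B[1, :9] = dNz
                B[2, 9:] = dNr
                B[3, 9:] = dNz
                B[4, :9] = N / rg
                w = wgt * detJ * rg
                Ke = w * (B.T @ Eq @ B)
                Bpe = w * np.outer(psi, trace_row @ B)

                dofs = np.concatenate([2 * ids, 2 * ids + 1])
                rows_K.append(np.repeat(dofs, 18))
                cols_K.append(np.tile(dofs, 18))
                vals_K.append(Ke.ravel())
                prow = np.array([self.p_index[g] for g in self.pconn[e]])
                rows_B.append(np.repeat(prow, 18))
                cols_B.append(np.tile(dofs, 4))
                vals_B.append(Bpe.ravel())

        K = sps.coo_matrix(
            (np.concatenate(vals_K), (np.concatenate(rows_K), np.concatenate(cols_K))),
            shape=(ndof_u, ndof_u)).tocsr()
        Bm = sps.coo_matrix(
            (np.concatenate(vals_B), (np.concatenate(rows_B), np.concatenate(cols_B))),
            shape=(ndof_p, ndof_u)).tocsr()

        if follower:
            K = K - self._follower_stiffness(follower, ndof_u)
        return K, Bm

    def _follower_stiffness(self, specs, ndof_u):
        """Surface stiffness  P * int_G (v_r u_r,r + v_z u_r,z) n_r r ds."""
        rows, cols, vals = [], [], []
        for edge_nodes, n_r, P in specs:
            if P == 0.0:
                continue
            for (a, b, c) in edge_nodes:        # 3-node edge along z
                ids = np.array([a, b, c])
                z = self.coords[ids, 0]
                rg = self.coords[ids[1], 1]
                h = abs(z[2] - z[0]) / 2        # parent half-length
                for xi, w in zip(_GAUSS3, _W3):
                    l = np.array([0.5 * xi * (xi - 1), 1 - xi * xi,
                                  0.5 * xi * (xi + 1)])
                    dl = np.array([xi - 0.5, -2 * xi, xi + 0.5]) / h
                    # u_r,z along the edge; u_r,r needs interior data, but
                    # on the wall u_r,r = -(u_r/r + u_z,z) (incompressible)
                    durdz = dl
                    durdr_r = -l / rg           # times u_r dofs
                    durdr_z = -dl               # times u_z dofs
                    w_s = w * h * rg * P * n_r
                    # v_r * u_r,r
                    rows.append(np.repeat(2 * ids, 3))
                    cols.append(np.tile(2 * ids, 3))
                    vals.append(w_s * np.outer(l, durdr_r).ravel())
                    rows.append(np.repeat(2 * ids, 3))
                    cols.append(np.tile(2 * ids + 1, 3))
                    vals.append(w_s * np.outer(l, durdr_z).ravel())
                    # v_z * u_r,z
                    rows.append(np.repeat(2 * ids + 1, 3))
                    cols.append(np.tile(2 * ids, 3))
                    vals.append(w_s * np.outer(l, durdz).ravel())
        if not rows:
            return sps.csr_matrix((ndof_u, ndof_u))
        return sps.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(ndof_u, ndof_u)).tocsr()

    # -- edges and loads --------------------------------------------------
    def wall_edges(self, which: str):
        """3-node edges along a wall ('inner' or 'outer'), base-grid ids."""
        nzf = 2 * self.nz + 1
        i = 0 if which == "inner" else 2 * self.nr
        out = []
        for ez in range(self.nz):
            j = 2 * ez
            out.append(tuple(i * nzf + (j + a) for a in range(3)))
        return out

    def face_edges(self, side: str):
        """Edges of the tear faces; 'lower' = r -> r_c-, 'upper' = r_c+."""
        nzf = 2 * self.nz + 1
        i = self.i_slit_fine
        out = []
        for ez in range(self.nz):
            j = 2 * ez
            zmid = self.zf[j + 1]
            if abs(zmid) < self.L_tear:
                ids = []
                for a in range(3):
                    key = (i, j + a)
                    if side == "upper" and key in self.dup_ids:
                        ids.append(self.dup_ids[key])
                    else:
                        ids.append(i * nzf + j + a)
                out.append(tuple(ids))
        return out

    def edge_load(self, edges, traction_r: float, ndof_u: int) -> np.ndarray:
        """Consistent nodal loads for a constant radial traction on edges."""
        f = np.zeros(ndof_u)
        for (a, b, c) in edges:
            ids = np.array([a, b, c])
            z = self.coords[ids, 0]
            rg = self.coords[ids[1], 1]
            h = abs(z[2] - z[0]) / 2
            for xi, w in zip(_GAUSS3, _W3):
                l = np.array([0.5 * xi * (xi - 1), 1 - xi * xi, 0.5 * xi * (xi + 1)])
                f[2 * ids] += w * h * rg * traction_r * l
        return f

    def end_uz_dofs(self) -> np.ndarray:
        """u_z dofs on the two end cross-sections z = +-Lz/2."""
        nzf = 2 * self.nz + 1
        ids = []
        for i in range(2 * self.nr + 1):
            ids.append(i * nzf + 0)
            ids.append(i * nzf + (nzf - 1))
        return 2 * np.array(sorted(ids)) + 1

    def solve(self, K, B, f, ends: str = "free") -> tuple[np.ndarray, np.ndarray]:
        """Solve the saddle system.

        ``ends='free'`` leaves the end sections traction-free and pins the
        rigid axial translation at one node; ``ends='roller'`` constrains
        u_z = 0 on both end sections, emulating the infinite tube held at
        fixed axial stretch far from the tear.
        """
        ndof_u, ndof_p = K.shape[0], B.shape[0]
        nzf = 2 * self.nz + 1
        if ends == "roller":
            pins = self.end_uz_dofs()
        elif ends == "free":
            pins = np.array([2 * (2 * self.nr * nzf + self.nz) + 1])
        else:
            raise ValueError("ends must be 'free' or 'roller'")
        A = sps.bmat([[K, B.T], [B, None]], format="lil")
        A[pins, :] = 0.0
        A[:, pins] = 0.0
        A[pins, pins] = 1.0
        rhs = np.concatenate([f, np.zeros(ndof_p)])
        rhs[pins] = 0.0
        x = spsolve(A.tocsr(), rhs)
        return x[:ndof_u], x[ndof_u:]


def _face_node_ids(mesh: AxisymmetricFEM, side: str) -> np.ndarray:
    ids = set()
    for e in mesh.face_edges(side):
        ids.update(e)
    return np.array(sorted(ids))


def fem_finite_tube(
    params: MaterialParams,
    r_in: float = 4.0, r_out: float = 6.0, r_c: float = 5.0,
    tube_length: float = 16.0, tear_length: float = 4.0,
    p: float = 0.1, nz: int = 80, nr: int = 20, ends: str = "roller",
) -> dict:
    """Finite-tube benchmark: pressure p on the lumen and both tear faces.

    The base state is the unloaded tube (no pre-stretch, no residual
    stress), so the incremental moduli are spatially uniform and the
    loads are pure (non-follower) pressures; tube ends are traction-free.
    Returns the maximum radial tear-face displacement and face profiles.
    """
    mesh = AxisymmetricFEM(r_in, r_out, r_c, tube_length, tear_length / 2, nz, nr)
    A_id = DeformationGradientDiag(1.0, 1.0, 1.0)
    A0 = incremental_moduli(params, A_id)
    q0 = -params.c          # sigma = 0 at the unloaded state
    K, B = mesh.assemble(lambda r: A0, lambda r: q0)

    ndof_u = 2 * mesh.n_nodes
    f = np.zeros(ndof_u)
    # lumen: solid outward normal -e_r, traction -p n = +p e_r
    f += mesh.edge_load(mesh.wall_edges("inner"), +p, ndof_u)
    # lower face: outward normal +e_r -> traction -p e_r; upper: +p e_r
    f += mesh.edge_load(mesh.face_edges("lower"), -p, ndof_u)
    f += mesh.edge_load(mesh.face_edges("upper"), +p, ndof_u)

    u, _ = mesh.solve(K, B, f, ends=ends)
    out = {}
    for side in ("lower", "upper"):
        ids = _face_node_ids(mesh, side)
        out[side] = {"z": mesh.coords[ids, 0], "u_r": u[2 * ids], "u_z": u[2 * ids + 1]}
    u_faces = np.concatenate([np.abs(out["lower"]["u_r"]), np.abs(out["upper"]["u_r"])])
    out["max_radial"] = float(u_faces.max())
    out["n_dof"] = ndof_u + B.shape[0]
    out["mesh"] = (nz, nr)
    return out


def fd_direct_solver(
    base: BaseState, tear_half_length: float, T_r: float,
    tube_length: float | None = None, nz: int = 80, nr: int = 20,
    ends: str = "roller",
) -> dict:
    """Direct-domain solve of the incremental tear problem.

    Discretises the incremental equations about the given finite base
    state on a long finite tube (default length 8 tear half-lengths),
    with the follower-pressure terms of the wall boundary conditions and
    the tear faces loaded by the constant incremental traction T_r
    (negative T_r opens the faces).  Truncation of the infinite tube and
    its traction-free ends are the leading model differences from the
    wavenumber-domain solver.
    """
    g = base.geom
    if tube_length is None:
        tube_length = 8.0 * tear_half_length
    mesh = AxisymmetricFEM(g.r_in, g.r_out, g.r_c, tube_length,
                           tear_half_length, nz, nr)
    p = base.params

    def moduli_at(r):
        R = np.sqrt(g.kappa * g.lam * (r**2 - g.r_in**2) + g.R_in**2)
        at = g.kappa * r / R
        A = DeformationGradientDiag(1.0 / (at * g.lam), at, g.lam)
        return incremental_moduli(p, A)

    follower = [
        (mesh.wall_edges("inner"), -1.0, base.P_in),
        (mesh.wall_edges("outer"), +1.0, g.P_ext),
    ]
    K, B = mesh.assemble(moduli_at, lambda r: float(base.q_at(r)), follower)
    ndof_u = 2 * mesh.n_nodes
    f = np.zeros(ndof_u)
    f += mesh.edge_load(mesh.face_edges("lower"), T_r, ndof_u)
    f += mesh.edge_load(mesh.face_edges("upper"), -T_r, ndof_u)

    u, _ = mesh.solve(K, B, f, ends=ends)
    lower = _face_node_ids(mesh, "lower")
    upper = _face_node_ids(mesh, "upper")
    # openings at matching z positions
    zl = mesh.coords[lower, 0]
    zu = mesh.coords[upper, 0]
    common, il, iu = np.intersect1d(np.round(zl, 10), np.round(zu, 10),
                                    return_indices=True)
    opening = u[2 * upper[iu]] - u[2 * lower[il]]
    return {"z": common, "opening": opening,
            "max_opening": float(opening.max()),
            "mesh": (nz, nr), "tube_length": tube_length}


def isotropic_limit_check(
    geom: TubeGeometry | None = None, n_stations: int = 40,
) -> OracleReport:
    """Far-field decay of the fibre-free (isotropic) tear fields.

    With k1 = 0, no residual stress and no pre-stretch, the dissection is
    a pressurised crack in an isotropic incompressible solid; wall
    displacements beyond the tear must decay algebraically.  The report
    carries the fitted decay exponent of |u| along the inner wall.
    """
    from .tear import (TearConfig, build_influence,
                       evaluate_surface_displacements, solve_opening)

    if geom is None:
        geom = TubeGeometry(r_in=4.0, r_out=6.0, r_c=5.0, R_in=4.0,
                            kappa=1.0, lam=1.0)
    params = MaterialParams(c=3.0, k1=1e-12, k2=0.8393, beta=np.pi / 3)
    cfg = TearConfig(L=1.0, N=10, k_max=12.0, N_k=180, station_extent=8)
    base = solve_radial_equilibrium(geom, params)
    infl = build_influence(base, cfg)
    n = infl.n_elements
    # pure face traction (no lumen-pressure mode, which is z-independent)
    U, W = solve_opening(infl, (np.full(n, -0.1), np.zeros(n)))
    profiles = evaluate_surface_displacements(infl, U, W)
    prof = profiles["rin"]
    z = prof["z"].values
    u = np.abs(prof["u"].values)
    sel = (z > 2.0 * cfg.L) & (u > 0)
    slope = np.polyfit(np.log(z[sel]), np.log(u[sel]), 1)[0]
    sym = float(np.abs(u - u[::-1]).max() / u.max())
    return OracleReport(
        quantity="inner-wall far-field decay exponent of |u|",
        solver_value=float(slope), oracle_value=-2.0,
        metadata={"z_range": (float(z[sel][0]), float(z[sel][-1])),
                  "symmetry_defect": sym, "config": cfg},
    )
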