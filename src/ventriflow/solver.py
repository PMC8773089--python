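"""Prescribed-motion incompressible flow in the moving left ventricle.

Incompressible Navier-Stokes in Arbitrary Lagrangian-Eulerian (ALE) form on
a moving tetrahedral mesh, discretized with equal-order P1/P1 elements and
SUPG/PSPG stabilization plus a grad-div term.  Time stepping is first-order
semi-implicit: the convective velocity is frozen at (u^n - w), all other
terms (viscous, pressure, resistive valve penalty) are implicit, so each
step is a single linear solve.

The closed mitral valve is a Resistive Immersed Implicit Surface (RIIS): a
penalty (R/eps) * delta_eps(phi) * (u - u_Gamma) is added to the momentum
equation inside a layer of half-width eps around the leaflet surface, which
drives the fluid velocity toward the leaflet velocity without the surface
being part of the mesh boundary.

Outlet sections carry a normal-traction condition -p_out(t) n derived from a
Wiggers-type systolic pressure waveform, with directional (backflow)
stabilization for truncated-domain outflow.

Units: mesh coordinates are millimetres (as produced by the imaging chain);
the solver converts to SI internally.  Velocities are m/s, pressures Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .fem import HarmonicExtension, apply_dirichlet, grad_basis, scalar_stiffness
from .meshing import OUTLET, WALL, TetMesh

MM = 1.0e-3  # mm -> m
MMHG = 133.322  # Pa per mmHg


@dataclass
class FluidProperties:
    """Blood as an incompressible Newtonian fluid."""

    density: float = 1.06e3  # kg/m^3
    viscosity: float = 3.5e-3  # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


class WiggersOutlet:
    """Systolic aortic pressure waveform derived from Wiggers diagrams.

    p(t) = diastolic + pulse * sin^2(pi t / T_sys), in mmHg, evaluated in Pa.
    """

    def __init__(self, t_sys: float, diastolic_mmhg: float = 80.0,
                 pulse_mmhg: float = 40.0):
        self.t_sys = float(t_sys)
        self.diastolic_mmhg = float(diastolic_mmhg)
        self.pulse_mmhg = float(pulse_mmhg)

    def __call__(self, t: float) -> float:
        s = np.sin(np.pi * np.clip(t, 0.0, self.t_sys) / self.t_sys)
        return (self.diastolic_mmhg + self.pulse_mmhg * s * s) * MMHG


class ConstantPressure:
    def __init__(self, p_pa: float):
        self.p_pa = float(p_pa)

    def __call__(self, t: float) -> float:
        return self.p_pa


@dataclass
class SolverConfig:
    dt: float = 2.0e-3  # s
    t_end: float = 0.4  # s (systole duration)
    beta_backflow: float = 0.2
    save_every: int = 5
    linear_solver: str = "stale"  # stale | direct
    refresh_every: int = 10  # max steps between LU refactorizations
    refresh_iters: int = 35  # GMRES iteration count triggering a refresh
    gmres_tol: float = 1.0e-9
    gmres_restart: int = 60

    def __post_init__(self):
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")


class RIISSurface:
    """Closed mitral leaflet surface immersed in the fluid domain.

    points/tris: triangulated leaflet sampling (mm, dense enough that the
    point spacing is below eps).  R is the surface resistance in
    kg/(m^2 s); eps the half-thickness of the smoothed delta layer (mm).
    The leaflet is advected with the extended domain displacement: each
    leaflet point is bound to its nearest mesh nodes and follows their
    motion, so the leaflet velocity u_Gamma coincides with the local ALE
    mesh velocity.
    """

    def __init__(self, points: np.ndarray, tris: np.ndarray,
                 resistance: float = 1.0e4, eps: float = 2.0):
        if resistance < 0 or eps <= 0:
            raise ValueError("resistance must be >= 0 and eps > 0")
        self.points0 = np.asarray(points, dtype=float)
        self.tris = np.asarray(tris, dtype=np.int64)
        self.resistance = float(resistance)
        self.eps = float(eps)
        self._bind_nodes = None
        self._bind_w = None
        self._candidates = None

    def bind(self, mesh_points: np.ndarray, k: int = 6) -> None:
        """Attach leaflet points to nearby mesh nodes (reference config)."""
        tree = cKDTree(mesh_points)
        d, idx = tree.query(self.points0, k=k)
        w = 1.0 / np.maximum(d, 1.0e-6)
        self._bind_nodes = idx
        self._bind_w = w / w.sum(axis=1, keepdims=True)
        # nodes that can ever fall inside the delta layer
        dn, _ = cKDTree(self.points0).query(mesh_points)
        self._candidates = np.flatnonzero(dn < self.eps + 5.0)

    def current_points(self, node_disp: np.ndarray) -> np.ndarray:
        """Leaflet positions under nodal displacement field (mm)."""
        if self._bind_nodes is None:
            return self.points0
        dp = np.einsum(
            "pk,pkj->pj", self._bind_w, node_disp[self._bind_nodes]
        )
        return self.points0 + dp

    def delta_at_nodes(self, mesh_points: np.ndarray,
                       leaflet_points: np.ndarray) -> np.ndarray:
        """Regularized delta [1/m] at mesh nodes; compact support |d|<eps."""
        out = np.zeros(len(mesh_points))
        cand = (
            self._candidates
            if self._candidates is not None
            else np.arange(len(mesh_points))
        )
        if len(cand) == 0:
            return out
        d, _ = cKDTree(leaflet_points).query(mesh_points[cand])
        x = d / self.eps
        inside = x < 1.0
        eps_m = self.eps * MM
        out[cand[inside]] = 0.75 / eps_m * (1.0 - x[inside] ** 2)
        return out


@dataclass
class FlowState:
    """Velocity/pressure snapshot on the current ALE configuration."""

    t: float
    u: np.ndarray  # (N, 3) m/s
    p: np.ndarray  # (N,) Pa
    points: np.ndarray  # (N, 3) mm, deformed configuration
    w: np.ndarray | None = None  # (N, 3) m/s mesh velocity


class NavierStokesALE:
    """Semi-implicit SUPG/PSPG-stabilized P1 solver on a moving mesh."""

    def __init__(
        self,
        mesh: TetMesh,
        props: FluidProperties,
        cfg: SolverConfig,
        riis: RIISSurface | None = None,
        pressure_bcs: list[tuple[int, object, bool]] | None = None,
        wall_tags: tuple[int, ...] = (WALL,),
    ):
        """pressure_bcs: list of (boundary tag, waveform, backflow_stab)."""
        self.mesh = mesh
        self.props = props
        self.cfg = cfg
        self.riis = riis
        if pressure_bcs is None:
            pressure_bcs = [(OUTLET, WiggersOutlet(cfg.t_end), True)]
        self.pressure_bcs = pressure_bcs
        self.n = len(mesh.points)
        self.tets = mesh.tets
        # dof layout: [ux (N), uy (N), uz (N), p (N)]
        n = self.n
        ld = np.empty((len(self.tets), 16), dtype=np.int64)
        for c in range(3):
            ld[:, 4 * c: 4 * c + 4] = self.tets + c * n
        ld[:, 12:16] = self.tets + 3 * n
        self._rows = np.repeat(ld, 16, axis=1).ravel()
        self._cols = np.tile(ld, (1, 16)).ravel()
        self.wall_nodes = np.unique(
            np.concatenate(
                [mesh.boundary_nodes(t) for t in wall_tags]
            )
        )
        self.wall_dofs = np.concatenate(
            [self.wall_nodes + c * n for c in range(3)]
        )
        self._bc_faces = {
            tag: mesh.boundary_faces[mesh.boundary_tags == tag]
            for tag, _, _ in pressure_bcs
        }
        if riis is not None:
            riis.bind(mesh.points)
        self._lu = None
        self._steps_since_factor = 0
        self._want_refresh = False
        self._step_count = 0
        self.u = np.zeros((n, 3))
        self.p = np.zeros(n)

    # -- assembly ----------------------------------------------------------
    def _assemble(self, pts_mm, u_n, w, t_new, dt):
        rho, mu = self.props.density, self.props.viscosity
        n = self.n
        pts = pts_mm * MM
        g, vol = grad_basis(pts, self.tets)
        if vol.min() <= 0:
            raise RuntimeError(
                "non-positive cell Jacobian in ALE configuration; "
                "reduce the time step or remesh"
            )
        E = len(self.tets)
        a_nod = u_n - w
        a_c = a_nod[self.tets].mean(axis=1)  # (E,3)
        ubar = u_n[self.tets].mean(axis=1)
        amag = np.linalg.norm(a_c, axis=1)
        h = (6.0 * np.sqrt(2.0) * vol) ** (1.0 / 3.0)
        tau_m = 1.0 / np.sqrt(
            (2.0 * rho / dt) ** 2
            + (2.0 * rho * amag / h) ** 2
            + (12.0 * mu / h**2) ** 2
        )
        tau_c = mu + 0.5 * rho * h * amag

        GG = np.einsum("eik,ejk->eij", g, g)
        AG = np.einsum("ek,ejk->ej", a_c, g)  # (E,4)
        V = vol[:, None, None]
        Mhat = (np.ones((4, 4)) + np.eye(4)) / 20.0

        Ke = np.zeros((E, 16, 16))
        # component-diagonal momentum block
        D = (
            (rho / dt) * V * Mhat
            + (rho * 0.25) * vol[:, None, None] * AG[:, None, :]
            + (tau_m * rho**2 * vol)[:, None, None]
            * AG[:, :, None] * AG[:, None, :]
            + (tau_m * rho**2 / dt * 0.25 * vol)[:, None, None]
            * AG[:, :, None] * np.ones((1, 1, 4))
            + mu * V * GG
        )
        for al in range(3):
            for be in range(3):
                blk = (
                    mu * V * np.einsum("ei,ej->eij", g[:, :, be], g[:, :, al])
                    + tau_c[:, None, None] * V
                    * np.einsum("ei,ej->eij", g[:, :, al], g[:, :, be])
                )
                if al == be:
                    blk = blk + D
                Ke[:, 4 * al: 4 * al + 4, 4 * be: 4 * be + 4] = blk
            # u(alpha)-p coupling: -(p, div v) + SUPG
            Ke[:, 4 * al: 4 * al + 4, 12:16] = (
                -0.25 * V * g[:, :, al][:, :, None] * np.ones((1, 1, 4))
                + (tau_m * rho * vol)[:, None, None]
                * AG[:, :, None] * g[:, :, al][:, None, :]
            )
            # p-u(alpha) coupling: (q, div u) + PSPG
            Ke[:, 12:16, 4 * al: 4 * al + 4] = (
                0.25 * V * g[:, :, al][:, None, :] * np.ones((1, 4, 1))
                + (tau_m * rho / dt * 0.25 * vol)[:, None, None]
                * g[:, :, al][:, :, None] * np.ones((1, 1, 4))
                + (tau_m * rho * vol)[:, None, None]
                * g[:, :, al][:, :, None] * AG[:, None, :]
            )
        Ke[:, 12:16, 12:16] = tau_m[:, None, None] * V * GG

        data = Ke.reshape(-1)
        rows, cols = self._rows, self._cols

        # rhs
        b = np.zeros(4 * n)
        u_loc = u_n[self.tets]  # (E,4,3)
        Mu = np.einsum("ij,ejc->eic", Mhat, u_loc)  # (E,4,3)
        for al in range(3):
            r_e = (rho / dt) * vol[:, None] * Mu[:, :, al] + (
                tau_m * rho**2 / dt * vol
            )[:, None] * AG * (ubar[:, al])[:, None]
            np.add.at(b, self.tets.ravel() + al * n, r_e.ravel())
        r_p = (tau_m * rho / dt * vol)[:, None] * np.einsum(
            "eik,ek->ei", g, ubar
        )
        np.add.at(b, self.tets.ravel() + 3 * n, r_p.ravel())

        # RIIS penalty (lumped nodal)
        if self.riis is not None and self.riis.resistance > 0:
            lumped = np.zeros(n)
            np.add.at(lumped, self.tets.ravel(),
                      np.repeat(vol * 0.25, 4))
            disp_mm = pts_mm - self.mesh.points
            leaf = self.riis.current_points(disp_mm)
            delta = self.riis.delta_at_nodes(pts_mm, leaf)
            coef = (self.riis.resistance / (self.riis.eps * MM)) * delta * lumped
            nz = np.flatnonzero(coef)
            if len(nz):
                extra_dofs = np.concatenate([nz + c * n for c in range(3)])
                rows = np.concatenate([rows, extra_dofs])
                cols = np.concatenate([cols, extra_dofs])
                data = np.concatenate([data, np.tile(coef[nz], 3)])
                for c in range(3):
                    b[nz + c * n] += coef[nz] * w[nz, c]

        # pressure (traction) boundaries + backflow stabilization
        for tag, waveform, backflow in self.pressure_bcs:
            faces = self._bc_faces[tag]
            if len(faces) == 0:
                continue
            area, nrm = self.mesh.face_areas_normals(faces, pts)
            p_out = float(waveform(t_new))
            for c in range(3):
                np.add.at(
                    b,
                    faces.ravel() + c * n,
                    np.repeat(-p_out * nrm[:, c] * area / 3.0, 3),
                )
            if backflow and self.cfg.beta_backflow > 0:
                un = np.einsum(
                    "fj,fj->f", u_n[faces].mean(axis=1), nrm
                )
                s = -0.5 * self.cfg.beta_backflow * rho * np.minimum(un, 0.0)
                coef = np.repeat(s * area / 3.0, 3)
                fdofs = faces.ravel()
                nzf = coef > 0
                if np.any(nzf):
                    for c in range(3):
                        rows = np.concatenate([rows, fdofs[nzf] + c * n])
                        cols = np.concatenate([cols, fdofs[nzf] + c * n])
                        data = np.concatenate([data, coef[nzf]])

        # wall Dirichlet: u = wall velocity (exact at nodes)
        wall_vals = np.concatenate(
            [w[self.wall_nodes, c] for c in range(3)]
        )
        rows, cols, data = apply_dirichlet(
            rows, cols, data, b, self.wall_dofs, wall_vals
        )
        A = sp.coo_matrix(
            (data, (rows, cols)), shape=(4 * n, 4 * n)
        ).tocsr()
        return A, b

    # -- linear solve ------------------------------------------------------
    def _solve(self, A, b):
        """Solve one step's linear system.

        The 'stale' strategy factorizes the matrix with SuperLU every few
        steps and reuses the factorization as a GMRES preconditioner in
        between: the system changes slowly (mesh motion and frozen
        convection), so a slightly outdated LU is an excellent
        preconditioner while costing only a triangular backsolve per
        iteration.
        """
        cfg = self.cfg
        if cfg.linear_solver == "direct":
            return spla.splu(A.tocsc()).solve(b)
        refresh = (
            self._lu is None
            or self._steps_since_factor >= cfg.refresh_every
            or self._want_refresh
        )
        if refresh:
            self._lu = spla.splu(A.tocsc())
            self._steps_since_factor = 0
            self._want_refresh = False
            return self._lu.solve(b)
        it = [0]
        M = spla.LinearOperator(A.shape, self._lu.solve)
        x0 = np.concatenate([self.u.T.ravel(), self.p])
        x, info = spla.gmres(
            A, b, x0=x0, M=M, rtol=cfg.gmres_tol, atol=0.0,
            restart=cfg.gmres_restart, maxiter=200,
            callback=lambda r: it.__setitem__(0, it[0] + 1),
            callback_type="pr_norm",
        )
        self._steps_since_factor += 1
        if info != 0:
            self._lu = spla.splu(A.tocsc())
            self._steps_since_factor = 0
            return self._lu.solve(b)
        if it[0] >= cfg.refresh_iters:
            self._want_refresh = True
        return x

    # -- stepping ----------------------------------------------------------
    def advance(self, pts_new_mm: np.ndarray, pts_old_mm: np.ndarray,
                t_new: float) -> FlowState:
        """One semi-implicit step onto the configuration pts_new_mm."""
        dt = self.cfg.dt
        w = (pts_new_mm - pts_old_mm) * MM / dt
        A, b = self._assemble(pts_new_mm, self.u, w, t_new, dt)
        x = self._solve(A, b)
        n = self.n
        self.u = x[: 3 * n].reshape(3, n).T.copy()
        self.p = x[3 * n:].copy()
        self._step_count += 1
        return FlowState(t_new, self.u.copy(), self.p.copy(),
                         pts_new_mm.copy(), w)

    def flux(self, faces: np.ndarray, pts_mm: np.ndarray,
             u: np.ndarray) -> float:
        """Volumetric flux through a face set [ml/s]."""
        area, nrm = self.mesh.face_areas_normals(faces, pts_mm * MM)
        um = u[faces].mean(axis=1)
        return float(np.einsum("f,fj,fj->", area, um, nrm) * 1.0e6)


def ale_lift(mesh: TetMesh) -> HarmonicExtension:
    """Harmonic lifting operator from the full boundary into the volume.

    Factorized once on the reference configuration; boundary displacement
    (mm) is extended to all nodes, defining the ALE map.
    """
    K = scalar_stiffness(mesh.points, mesh.tets)
    return HarmonicExtension(K, mesh.boundary_nodes())


def interpolate_p1(mesh: TetMesh, pts_nodes_mm: np.ndarray,
                   query_mm: np.ndarray,
                   fields: list[np.ndarray]) -> list[np.ndarray]:
    """Finite-element (P1) interpolation of nodal fields at arbitrary points.

    Points are located by testing the barycentric coordinates of nearby
    candidate cells (nearest tet centroids first); points that escape the
    mesh by round-off use their best (least-negative) candidate.
    """
    ctr = pts_nodes_mm[mesh.tets].mean(axis=1)
    k = min(40, len(mesh.tets))
    _, cand = cKDTree(ctr).query(query_mm, k=k)
    cand = np.atleast_2d(cand)
    nq = len(query_mm)
    best_bary = np.full((nq, 4), -np.inf)
    best_tet = np.zeros(nq, dtype=np.int64)
    found = np.zeros(nq, dtype=bool)
    for j in range(k):
        todo = np.flatnonzero(~found)
        if len(todo) == 0:
            break
        tets_j = cand[todo, j]
        a = pts_nodes_mm[mesh.tets[tets_j, 0]]
        T = np.stack(
            [pts_nodes_mm[mesh.tets[tets_j, i]] - a for i in (1, 2, 3)], axis=-1
        )
        rhs = query_mm[todo] - a
        lam = np.linalg.solve(T, rhs[..., None])[..., 0]
        bary = np.column_stack([1.0 - lam.sum(axis=1), lam])
        score = bary.min(axis=1)
        better = score > best_bary[todo].min(axis=1)
        bt = todo[better]
        best_bary[bt] = bary[better]
        best_tet[bt] = tets_j[better]
        inside = score >= -1.0e-9
        found[todo[inside]] = True
    verts = mesh.tets[best_tet]
    out = []
    for f in fields:
        vals = np.einsum("qk,qk...->q...", best_bary, f[verts])
        out.append(vals)
    return out


def riis_flux(state: FlowState, riis: RIISSurface,
              mesh: TetMesh) -> float:
    """Flux of (u - u_Gamma) through the leaflet surface [ml/s].

    The discrete velocity is interpolated (P1) at leaflet triangle
    centroids; the leaflet velocity equals the bound mesh motion, so a
    perfectly sealing valve yields zero flux.
    """
    disp = state.points - mesh.points
    pts = riis.current_points(disp)
    ctr = pts[riis.tris].mean(axis=1)
    e1 = pts[riis.tris[:, 1]] - pts[riis.tris[:, 0]]
    e2 = pts[riis.tris[:, 2]] - pts[riis.tris[:, 0]]
    nv = np.cross(e1, e2)
    a2 = np.linalg.norm(nv, axis=1)
    nhat = nv / np.where(a2 > 0, a2, 1.0)[:, None]
    area = 0.5 * a2 * MM * MM
    w = state.w if state.w is not None else np.zeros_like(state.u)
    u_c, ug_c = interpolate_p1(mesh, state.points, ctr, [state.u, w])
    rel = u_c - ug_c
    return float(np.einsum("f,fj,fj->", area, rel, nhat) * 1.0e6)
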