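"""Hemodynamic indicators of LVOT obstruction.

From the saved flow states this module derives every quantity used to grade
the obstruction: global volumetry (EDV/ESV/SV/EF), the maximum aortic
velocity U(t) with its systolic median U_thr and the obstruction duration
(largest connected interval with U(t) > U_thr), the pressure difference
Δp = p - p_out relative to the outlet section, the Δp and wall-shear-stress
profiles along a line running down the septum from the right-coronary
ostium to the apex, the intraventricular gradient max(Δp) - min(Δp) on that
line, the WSS field and the Q-criterion vortex indicator, and the Reynolds
number in the aortic root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AORTIC_ROOT, ASCENDING, ComputationalDomain
from .meshing import OUTLET, WALL, TetMesh
from .solver import MM, MMHG, FlowState, FluidProperties


# ---------------------------------------------------------------------------
# volumetry
# ---------------------------------------------------------------------------


def ef_metrics(edv: float, esv: float) -> tuple[float, float]:
    """Stroke volume [ml] and ejection fraction [%] from EDV/ESV [ml]."""
    if not edv > esv > 0:
        raise ValueError("requires EDV > ESV > 0")
    sv = edv - esv
    return sv, 100.0 * sv / edv


def max_volume_discrepancy(
    reconstructed: np.ndarray, clinical: np.ndarray
) -> float:
    """max_i |V_rec,i - V_clin,i| / V_clin,i over patients (fraction)."""
    r = np.asarray(reconstructed, dtype=float)
    c = np.asarray(clinical, dtype=float)
    return float(np.max(np.abs(r - c) / c))


# ---------------------------------------------------------------------------
# U(t) and obstruction duration
# ---------------------------------------------------------------------------


@dataclass
class ObstructionReport:
    times: np.ndarray  # s
    U: np.ndarray  # m/s
    U_thr: float  # m/s, median of U over systole
    duration: float  # s, largest connected interval with U > U_thr
    peak_velocity: float  # m/s
    peak_time: float  # s


def aortic_node_set(mesh: TetMesh,
                    tags: tuple[int, ...] = (AORTIC_ROOT, ASCENDING)) -> np.ndarray:
    sel = np.isin(mesh.cell_tags, tags)
    if not sel.any():
        raise ValueError("no cells carry the requested subdomain tags")
    return np.unique(mesh.tets[sel])


def max_aortic_velocity(
    states: list[FlowState], mesh: TetMesh,
    tags: tuple[int, ...] = (AORTIC_ROOT, ASCENDING),
) -> tuple[np.ndarray, np.ndarray]:
    """U(t): maximum velocity magnitude over the aortic subdomain nodes."""
    nodes = aortic_node_set(mesh, tags)
    times = np.array([s.t for s in states])
    U = np.array(
        [np.linalg.norm(s.u[nodes], axis=1).max() for s in states]
    )
    return times, U


def _super_threshold_intervals(times, f):
    """Maximal intervals where the piecewise-linear interpolant is > 0."""
    intervals = []
    start = None
    for i in range(len(times) - 1):
        f0, f1, t0, t1 = f[i], f[i + 1], times[i], times[i + 1]
        if f0 > 0 and start is None:
            start = t0
        if f0 > 0 and f1 <= 0:
            tc = t0 + (t1 - t0) * f0 / (f0 - f1)
            intervals.append((start if start is not None else t0, tc))
            start = None
        elif f0 <= 0 and f1 > 0:
            start = t0 + (t1 - t0) * f0 / (f0 - f1) if f1 != f0 else t1
    if f[-1] > 0:
        intervals.append((start if start is not None else times[-1], times[-1]))
    # a sample sitting exactly on the threshold splits the super-level set
    # at a single point; such zero-length gaps do not interrupt the interval
    tol = 1.0e-12 * max(1.0, abs(times[-1] - times[0]))
    merged = []
    for a, b in intervals:
        if merged and a - merged[-1][1] <= tol:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def obstruction_duration(
    times: np.ndarray, U: np.ndarray,
    systole: tuple[float, float] | None = None,
) -> ObstructionReport:
    """Threshold U_thr (median of U over systole) and obstruction duration.

    The sampled U(t) is interpolated piecewise-linearly, so the measured
    duration is not quantized to the output interval; 'above threshold' is
    strict, hence a constant series has zero duration.
    """
    times = np.asarray(times, dtype=float)
    U = np.asarray(U, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples over systole")
    if systole is not None:
        sel = (times >= systole[0]) & (times <= systole[1])
    else:
        sel = np.ones(len(times), dtype=bool)
    thr = float(np.median(U[sel]))
    iv = _super_threshold_intervals(times[sel], U[sel] - thr)
    duration = max((b - a for a, b in iv), default=0.0)
    ipk = int(np.argmax(U))
    return ObstructionReport(
        times=times, U=U, U_thr=thr, duration=float(duration),
        peak_velocity=float(U[ipk]), peak_time=float(times[ipk]),
    )


# ---------------------------------------------------------------------------
# pressure difference
# ---------------------------------------------------------------------------


def pressure_difference(state: FlowState, mesh: TetMesh) -> np.ndarray:
    """Δp = p - <p>_Σout, in mmHg (area-weighted outlet mean)."""
    faces = mesh.boundary_faces[mesh.boundary_tags == OUTLET]
    area, _ = mesh.face_areas_normals(faces, state.points)
    p_face = state.p[faces].mean(axis=1)
    p_out = float((area * p_face).sum() / area.sum())
    return (state.p - p_out) / MMHG


# ---------------------------------------------------------------------------
# septal line
# ---------------------------------------------------------------------------


@dataclass
class SeptalLineProfile:
    """Boundary polyline from the right-coronary ostium to the apex.

    ``s`` is the arclength normalized by the total ostium-to-apex length;
    interpolation weights (edge node pairs + parameter) allow sampling any
    nodal field along the line.  ``s_annulus`` marks point A, where the
    line crosses the aortic annulus level.
    """

    points: np.ndarray  # (M, 3) mm, ordered from ostium to apex
    s: np.ndarray  # (M,) in [0, 1]
    edge_nodes: np.ndarray  # (M, 2) boundary node pair of each point
    edge_t: np.ndarray  # (M,) interpolation parameter on the edge
    s_annulus: float

    def sample(self, nodal_field: np.ndarray) -> np.ndarray:
        f = np.asarray(nodal_field)
        t = self.edge_t if f.ndim == 1 else self.edge_t[:, None]
        return (1.0 - t) * f[self.edge_nodes[:, 0]] + t * f[self.edge_nodes[:, 1]]


def septal_line(
    mesh: TetMesh,
    points: np.ndarray,
    ostium: np.ndarray,
    apex: np.ndarray,
    septal_center: np.ndarray,
    z_annulus: float | None = None,
) -> SeptalLineProfile:
    """Intersect the boundary with the plane through the three landmarks.

    The connected branch running from the ostium through the septal wall to
    the apex is kept and parameterized by normalized arclength (0 at the
    ostium, 1 at the apex).
    """
    n = np.cross(apex - ostium, septal_center - ostium)
    nn = np.linalg.norm(n)
    if nn < 1.0e-9:
        raise ValueError("collinear landmarks do not define a plane")
    n = n / nn
    faces = mesh.boundary_faces
    sd = (points - ostium) @ n
    # nodes exactly on the plane (common on structured meshes) are nudged to
    # one side so the intersection polyline stays edge-transversal
    sd = np.where(np.abs(sd) < 1.0e-9, 1.0e-9, sd)
    fs = sd[faces]
    cut = (fs.max(axis=1) > 0) & (fs.min(axis=1) < 0)
    segs, seg_edges, seg_ts = [], [], []
    for f in faces[cut]:
        crossings = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            sa, sb = sd[f[a]], sd[f[b]]
            if (sa > 0) != (sb > 0):
                t = sa / (sa - sb)
                crossings.append((f[a], f[b], t))
        if len(crossings) == 2:
            segs.append(crossings)
    if not segs:
        raise ValueError("plane does not intersect the boundary")
    # chain segments into polylines via shared-edge keys
    def key(c):
        a, b, t = c
        return (min(a, b), max(a, b))

    adj: dict = {}
    for i, (c0, c1) in enumerate(segs):
        for c in (c0, c1):
            adj.setdefault(key(c), []).append(i)
    pt_of = {}
    for c0, c1 in segs:
        for c in (c0, c1):
            a, b, t = c
            if key(c) not in pt_of:
                tt = t if a < b else 1.0 - t
                aa, bb = min(a, b), max(a, b)
                pt_of[key(c)] = (
                    (1 - tt) * points[aa] + tt * points[bb], (aa, bb), tt
                )
    # walk loops
    visited = np.zeros(len(segs), dtype=bool)
    loops = []
    for i0 in range(len(segs)):
        if visited[i0]:
            continue
        loop_keys = [key(segs[i0][0])]
        cur, nxt_key = i0, key(segs[i0][1])
        visited[i0] = True
        while True:
            loop_keys.append(nxt_key)
            cands = [j for j in adj.get(nxt_key, []) if not visited[j]]
            if not cands:
                break
            cur = cands[0]
            visited[cur] = True
            k0, k1 = key(segs[cur][0]), key(segs[cur][1])
            nxt_key = k1 if k0 == nxt_key else k0
        loops.append(loop_keys)
    # choose the loop closest to the landmarks
    def loop_pts(keys):
        return np.array([pt_of[k][0] for k in keys])

    best = min(
        loops,
        key=lambda ks: sum(
            np.min(np.linalg.norm(loop_pts(ks) - lm, axis=1))
            for lm in (ostium, apex, septal_center)
        ),
    )
    lp = loop_pts(best)
    i_ost = int(np.argmin(np.linalg.norm(lp - ostium, axis=1)))
    i_apx = int(np.argmin(np.linalg.norm(lp - apex, axis=1)))
    # two arcs between ostium and apex; keep the one through the septum
    idx = np.arange(len(lp))
    if i_ost <= i_apx:
        arc1 = idx[i_ost: i_apx + 1]
        arc2 = np.concatenate([idx[i_apx:], idx[: i_ost + 1]])[::-1]
    else:
        arc1 = idx[i_apx: i_ost + 1][::-1]
        arc2 = np.concatenate([idx[i_ost:], idx[: i_apx + 1]])
    d1 = np.min(np.linalg.norm(lp[arc1] - septal_center, axis=1))
    d2 = np.min(np.linalg.norm(lp[arc2] - septal_center, axis=1))
    arc = arc1 if d1 <= d2 else arc2
    pts = lp[arc]
    if np.min(np.linalg.norm(pts - septal_center, axis=1)) > 10.0:
        raise ValueError("septal branch does not pass near the septal center")
    # drop duplicate crossings (plane passing through mesh nodes)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg_len > 1.0e-6])
    arc = arc[keep]
    pts = pts[keep]
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = s / s[-1]
    edges = np.array([pt_of[best[i]][1] for i in arc])
    ts = np.array([pt_of[best[i]][2] for i in arc])
    if z_annulus is not None:
        zs = pts[:, 2]
        below = np.flatnonzero(zs <= z_annulus)
        s_ann = float(s[below[0]]) if len(below) else float("nan")
    else:
        s_ann = float("nan")
    return SeptalLineProfile(points=pts, s=s, edge_nodes=edges, edge_t=ts,
                             s_annulus=s_ann)


def intraventricular_gradient(profile: SeptalLineProfile,
                              dp_mmhg: np.ndarray) -> float:
    """max(Δp) - min(Δp) along the septal line [mmHg]."""
    vals = profile.sample(dp_mmhg)
    return float(vals.max() - vals.min())


# ---------------------------------------------------------------------------
# velocity-gradient quantities: WSS and Q-criterion
# ---------------------------------------------------------------------------


_patch_cache: dict[int, dict] = {}


def _node_patches(mesh: TetMesh, nodes: np.ndarray) -> list[np.ndarray]:
    """Edge-connected node patch per query node (cached per mesh)."""
    key = id(mesh)
    cache = _patch_cache.setdefault(key, {})
    missing = [v for v in nodes if v not in cache]
    if missing:
        node_tets: dict[int, list[int]] = {v: [] for v in missing}
        want = np.zeros(len(mesh.points), dtype=bool)
        want[missing] = True
        sel = want[mesh.tets].any(axis=1)
        for e in np.flatnonzero(sel):
            for v in mesh.tets[e]:
                if v in node_tets:
                    node_tets[v].append(e)
        for v in missing:
            cache[v] = np.unique(mesh.tets[node_tets[v]])
    return [cache[v] for v in nodes]


def _node_gradients(state: FlowState, mesh: TetMesh,
                    nodes: np.ndarray) -> np.ndarray:
    """Velocity gradient [1/s] at given nodes by local least squares.

    P1 velocity gradients are cellwise constant; a linear fit over each
    node's edge-connected patch recovers a superconvergent nodal value.
    """
    pts = state.points * MM
    patches = _node_patches(mesh, nodes)
    grads = np.empty((len(nodes), 3, 3))
    for i, (v, patch) in enumerate(zip(nodes, patches)):
        X = pts[patch] - pts[v]
        A = np.hstack([np.ones((len(patch), 1)), X])
        AtA = A.T @ A
        Atb = A.T @ state.u[patch]
        coef = np.linalg.solve(AtA, Atb)
        grads[i] = coef[1:].T  # grads[i][a, b] = d u_a / d x_b
    return grads


def wall_normals(mesh: TetMesh, points: np.ndarray,
                 nodes: np.ndarray) -> np.ndarray:
    """Outward unit normals at wall nodes (area-weighted face average)."""
    faces = mesh.boundary_faces[mesh.boundary_tags == WALL]
    area, nrm = mesh.face_areas_normals(faces, points)
    acc = np.zeros((len(points), 3))
    for k in range(3):
        np.add.at(acc, faces[:, k], nrm * area[:, None])
    out = acc[nodes]
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def wss(state: FlowState, mesh: TetMesh,
        props: FluidProperties) -> tuple[np.ndarray, np.ndarray]:
    """Wall shear stress vectors [Pa] at wall nodes.

    t = mu (grad u + grad u^T) n;  WSS = t - (t.n) n.
    Returns (wall node ids, WSS vectors).
    """
    nodes = mesh.boundary_nodes(WALL)
    G = _node_gradients(state, mesh, nodes)
    n = wall_normals(mesh, state.points, nodes)
    S2 = G + np.transpose(G, (0, 2, 1))
    t = props.viscosity * np.einsum("nab,nb->na", S2, n)
    tn = np.einsum("na,na->n", t, n)
    return nodes, t - tn[:, None] * n


def q_criterion(state: FlowState, mesh: TetMesh) -> np.ndarray:
    """Nodal Q-criterion [1/s^2]: Q = (||W||^2 - ||S||^2) / 2.

    S and W are the symmetric and antisymmetric parts of grad u (Frobenius
    norms); Q > 0 marks rotation-dominated flow.  Cellwise values are
    volume-averaged to the nodes.
    """
    from .fem import grad_basis

    pts = state.points * MM
    g, vol = grad_basis(pts, mesh.tets)
    Gc = np.einsum("eia,eib->eab", state.u[mesh.tets], g)  # du_a/dx_b
    S = 0.5 * (Gc + np.transpose(Gc, (0, 2, 1)))
    W = 0.5 * (Gc - np.transpose(Gc, (0, 2, 1)))
    Qc = 0.5 * (
        np.einsum("eab,eab->e", W, W) - np.einsum("eab,eab->e", S, S)
    )
    num = np.zeros(len(state.points))
    den = np.zeros(len(state.points))
    np.add.at(num, mesh.tets.ravel(), np.repeat(Qc * vol, 4))
    np.add.at(den, mesh.tets.ravel(), np.repeat(vol, 4))
    return num / np.where(den > 0, den, 1.0)


def reynolds_number(U: float, diameter_mm: float,
                    props: FluidProperties) -> float:
    """Re = rho U D / mu with D the aortic-root diameter."""
    return props.density * U * diameter_mm * MM / props.viscosity
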