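"""Domain completion: parametric aorta/mitral templates, motion extension,
and simulation meshing.

Cine-MRI reconstructs the LV cavity only; the simulation domain additionally
needs an ascending aorta and a closed mitral valve.  Both are generated as
fully parametric templates adapted to the reconstructed annuli: the aorta is
a circle-swept tube with a Valsalva-sinus bulge followed by a straight
ascending segment ending at the planar outlet section, and the mitral valve
is a coapted leaflet surface spanning the (saddle-shaped) mitral annulus and
bulging toward the ventricle.  The endocardial displacement recovered by
registration is spread over the remaining boundary (templates and outlet)
by a harmonic extension on the boundary surface, with zero displacement at
the outlet section.

The volume mesh is produced by the structured swept-tube mesher in
:mod:`ventriflow.meshing`, with the axial layer spacing refined in the LVOT
and valve region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline, RegularGridInterpolator

from .fem import surface_stiffness, HarmonicExtension
from .meshing import OUTLET, WALL, TetMesh, build_swept_mesh, graded_layers
from .reconstruction import DisplacementField

# subdomain tags
VENTRICLE, LVOT, AORTIC_ROOT, ASCENDING = 1, 2, 3, 4


@dataclass
class AnnulusFit:
    """Least-squares plane + circle fit of a valve annulus ring."""

    center: np.ndarray  # (3,)
    normal: np.ndarray  # (3,) unit
    radius: float  # mm
    ring_points: np.ndarray  # (K, 3) ordered
    saddle_height: np.ndarray  # mm, amplitude of the cos(2*phi) out-of-plane mode
    plane_rms: float  # mm
    radial_rms: float  # mm


def fit_annulus(ring_points: np.ndarray) -> AnnulusFit:
    """Fit a plane and an effective circle to ordered annulus ring points."""
    pts = np.asarray(ring_points, dtype=float)
    if len(pts) < 6:
        raise ValueError("annulus fit needs at least 6 points")
    center = pts.mean(axis=0)
    rel = pts - center
    _, s, vt = np.linalg.svd(rel, full_matrices=False)
    if s[1] < 1.0e-9 * s[0]:
        raise ValueError("degenerate (collinear) annulus points")
    normal = vt[2]
    e1, e2 = vt[0], vt[1]
    u = rel @ e1
    v = rel @ e2
    h = rel @ normal
    radius = float(np.hypot(u, v).mean())
    phi = np.arctan2(v, u)
    a = 2.0 * np.mean(h * np.cos(2 * phi))
    b = 2.0 * np.mean(h * np.sin(2 * phi))
    return AnnulusFit(
        center=center,
        normal=normal,
        radius=radius,
        ring_points=pts,
        saddle_height=float(np.hypot(a, b)),
        plane_rms=float(np.sqrt(np.mean(h**2))),
        radial_rms=float(np.sqrt(np.mean((np.hypot(u, v) - radius) ** 2))),
    )


@dataclass
class TemplateConfig:
    """Parametric aorta / mitral template dimensions (mm)."""

    lvot_taper_length: float = 12.0
    sinus_radius_factor: float = 1.4
    sinus_height: float = 20.0
    ascending_length: float = 40.0
    mitral_depth: float = 6.0
    leaflet_n_rho: int = 12
    leaflet_n_phi: int = 48


class ComputationalDomain:
    """LV cavity + LVOT + aortic root + ascending aorta, with landmarks.

    Geometry lives in a 'domain frame' whose z axis is the LV long axis
    (apex at the bottom, outlet at the top); ``to_world``/``to_domain``
    convert to image coordinates.  The mitral leaflet surface is carried as
    an immersed triangulated surface, not part of the mesh boundary.
    """

    def __init__(self, radius_fn, z_apex, z_base, z_ann, z_sinus_top, z_out,
                 rotation, landmarks, leaflet_points, leaflet_tris,
                 aortic_fit, mitral_fit):
        self.radius_fn = radius_fn
        self.z_apex = z_apex
        self.z_base = z_base
        self.z_ann = z_ann
        self.z_sinus_top = z_sinus_top
        self.z_out = z_out
        self.rotation = rotation  # world -> domain: x_dom = R (x_w) - shift
        self.landmarks = landmarks  # domain-frame points
        self.leaflet_points = leaflet_points
        self.leaflet_tris = leaflet_tris
        self.aortic_fit = aortic_fit
        self.mitral_fit = mitral_fit
        self.mesh: TetMesh | None = None

    # frame changes ---------------------------------------------------------
    def to_world(self, pts_dom: np.ndarray) -> np.ndarray:
        R, shift = self.rotation
        return (np.asarray(pts_dom) + shift) @ R

    def to_domain(self, pts_w: np.ndarray) -> np.ndarray:
        R, shift = self.rotation
        return np.asarray(pts_w) @ R.T - shift

    def vectors_to_domain(self, vec_w: np.ndarray) -> np.ndarray:
        R, _ = self.rotation
        return np.asarray(vec_w) @ R.T


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Orthogonal matrix R with R @ axis = +z (rows are the new basis)."""
    a = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    s = np.linalg.norm(v)
    if s < 1.0e-12:
        return np.eye(3) if a[2] > 0 else np.diag([1.0, -1.0, -1.0])
    c = float(a @ z)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _radius_table(verts_dom, z_apex, z_base, n_theta=48, n_z=48):
    """Max-radius-per-bin lookup of the cavity wall, smoothed, gap-filled."""
    th = np.arctan2(verts_dom[:, 1], verts_dom[:, 0])
    r = np.hypot(verts_dom[:, 0], verts_dom[:, 1])
    z = verts_dom[:, 2]
    it = np.clip(((th + np.pi) / (2 * np.pi) * n_theta).astype(int), 0, n_theta - 1)
    zedges = np.linspace(z_apex, z_base, n_z + 1)
    iz = np.clip(np.digitize(z, zedges) - 1, 0, n_z - 1)
    table = np.zeros((n_theta, n_z))
    np.maximum.at(table, (it, iz), r)
    # fill empty bins from neighbours along z, then along theta
    for _ in range(n_z):
        empty = table == 0
        if not empty.any():
            break
        shifted = np.maximum(np.roll(table, 1, axis=1), np.roll(table, -1, axis=1))
        table[empty] = shifted[empty]
    for _ in range(n_theta):
        empty = table == 0
        if not empty.any():
            break
        shifted = np.maximum(np.roll(table, 1, axis=0), np.roll(table, -1, axis=0))
        table[empty] = shifted[empty]
    table = ndimage.uniform_filter(table, size=(3, 3), mode="wrap")
    zc = 0.5 * (zedges[:-1] + zedges[1:])
    # periodic padding in theta for interpolation
    thc = (np.arange(n_theta) + 0.5) * 2 * np.pi / n_theta - np.pi
    thp = np.concatenate([[thc[0] - 2 * np.pi / n_theta], thc,
                          [thc[-1] + 2 * np.pi / n_theta]])
    tp = np.vstack([table[-1:], table, table[:1]])
    return RegularGridInterpolator(
        (thp, zc), tp, bounds_error=False, fill_value=None
    )


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def attach_templates(
    endo_verts: np.ndarray,
    endo_faces: np.ndarray,
    aortic_fit: AnnulusFit,
    mitral_fit: AnnulusFit,
    config: TemplateConfig | None = None,
    apex_hint: np.ndarray | None = None,
    septal_hint: np.ndarray | None = None,
) -> ComputationalDomain:
    """Complete the reconstructed LV with aorta and mitral templates.

    The LV long axis runs from the apex to the aortic annulus center; the
    cavity wall radius is tabulated from the reconstructed surface, blended
    into the annulus circle over the LVOT, continued by Valsalva sinuses
    (radius factor ~1.4) and a straight ascending segment terminated by the
    planar outlet.
    """
    cfg = config or TemplateConfig()
    if apex_hint is None:
        apex_hint = endo_verts[np.argmin(endo_verts[:, 2])]
    axis = aortic_fit.center - apex_hint
    if np.linalg.norm(axis) < 1.0:
        raise ValueError("degenerate long axis")
    R = _rotation_to_z(axis)
    ann_dom = aortic_fit.center @ R.T
    shift = np.array([ann_dom[0], ann_dom[1], 0.0])
    rot = (R, shift)
    verts_dom = endo_verts @ R.T - shift
    z_base = float((aortic_fit.center @ R.T - shift)[2])
    z_apex = float(verts_dom[:, 2].min()) + 0.5
    z_ann = z_base + cfg.lvot_taper_length
    z_sinus_top = z_ann + cfg.sinus_height
    z_out = z_sinus_top + cfg.ascending_length
    r_ao = aortic_fit.radius

    table = _radius_table(verts_dom, z_apex, z_base)

    def radius_fn(theta, z):
        theta = np.asarray(theta, dtype=float)
        zz = np.broadcast_to(np.asarray(z, dtype=float), theta.shape)
        r_lv = table(np.stack([theta, np.clip(zz, z_apex, z_base)], axis=-1))
        s = _smoothstep((zz - z_base) / cfg.lvot_taper_length)
        r = (1 - s) * r_lv + s * r_ao
        in_sinus = (zz >= z_ann) & (zz < z_sinus_top)
        xi = (zz - z_ann) / cfg.sinus_height
        sinus = 1.0 + (cfg.sinus_radius_factor - 1.0) * np.sin(np.pi * np.clip(xi, 0, 1))
        r = np.where(in_sinus, r_ao * sinus, r)
        r = np.where(zz >= z_sinus_top, r_ao, r)
        return r

    # mitral leaflet: coapted surface over the saddle annulus, bulging into
    # the ventricle, immersed in the fluid domain
    ring_dom = mitral_fit.ring_points @ R.T - shift
    leaflet_pts, leaflet_tris = _leaflet_surface(
        ring_dom, cfg.mitral_depth, cfg.leaflet_n_rho, cfg.leaflet_n_phi
    )
    # safety clamp: the immersed surface stays strictly inside the fluid
    th_l = np.arctan2(leaflet_pts[:, 1], leaflet_pts[:, 0])
    r_l = np.hypot(leaflet_pts[:, 0], leaflet_pts[:, 1])
    r_wall = radius_fn(th_l, np.clip(leaflet_pts[:, 2], z_apex, z_out))
    r_max = np.maximum(r_wall - 0.4, 0.5)
    over = r_l > r_max
    if np.any(r_l[over] - r_max[over] > 6.0):
        raise ValueError("mitral template does not fit inside the LV")
    scale = np.where(over, r_max / np.maximum(r_l, 1e-9), 1.0)
    leaflet_pts[:, 0] *= scale
    leaflet_pts[:, 1] *= scale

    septal = (
        septal_hint @ R.T - shift
        if septal_hint is not None
        else np.array([float(radius_fn(np.array(0.0), 0.5 * (z_apex + z_base))),
                       0.0, 0.5 * (z_apex + z_base)])
    )
    th_septal = float(np.arctan2(septal[1], septal[0]))
    landmarks = {
        "apex": np.array([0.0, 0.0, z_apex]),
        "septal_center": septal,
        # right-coronary-ostium analog: septal-most point of the aortic
        # annulus ring
        "rc_ostium": np.array(
            [r_ao * np.cos(th_septal), r_ao * np.sin(th_septal), z_ann]
        ),
        "annulus_point_A": np.array(
            [r_ao * np.cos(th_septal), r_ao * np.sin(th_septal), z_ann]
        ),
    }
    dom = ComputationalDomain(
        radius_fn, z_apex, z_base, z_ann, z_sinus_top, z_out, rot,
        landmarks, leaflet_pts, leaflet_tris, aortic_fit, mitral_fit,
    )
    return dom


def _leaflet_surface(ring_dom, depth, n_rho, n_phi):
    """Triangulated coapted-leaflet cap spanning a closed ring."""
    K = len(ring_dom)
    phi_src = np.linspace(0, 1, K, endpoint=False)
    phi_tgt = np.linspace(0, 1, n_phi, endpoint=False)
    ring = np.stack(
        [np.interp(phi_tgt, phi_src, ring_dom[:, c], period=1.0)
         for c in range(3)], axis=-1
    )
    center = ring.mean(axis=0)
    pts = [center[None, :]]
    for rho in np.linspace(1.0 / n_rho, 1.0, n_rho):
        layer = center + rho * (ring - center)
        layer[:, 2] -= depth * (1.0 - rho**2)
        pts.append(layer)
    pts = np.vstack(pts)
    pts[0, 2] -= depth
    tris = []
    for k in range(n_phi):  # center fan
        tris.append((0, 1 + k, 1 + (k + 1) % n_phi))
    for j in range(n_rho - 1):
        o0 = 1 + j * n_phi
        o1 = 1 + (j + 1) * n_phi
        for k in range(n_phi):
            k1 = (k + 1) % n_phi
            tris.append((o0 + k, o1 + k, o0 + k1))
            tris.append((o0 + k1, o1 + k, o1 + k1))
    return pts, np.asarray(tris, dtype=np.int64)


def build_mesh(
    domain: ComputationalDomain,
    h_coarse: float = 4.0,
    h_fine: float = 1.5,
    refine_margin: float = 10.0,
    max_cells: int = 200_000,
) -> TetMesh:
    """Tetrahedral simulation mesh with LVOT/valve refinement.

    Axial layers are spaced ``h_coarse`` in the ventricle body and the
    ascending aorta and ``h_fine`` between (base - margin) and the top of
    the Valsalva sinuses; the in-plane resolution follows the local radius,
    which naturally refines the narrow LVOT.
    """
    d = domain
    r_max = float(
        np.max(d.radius_fn(np.linspace(-np.pi, np.pi, 64),
                           0.3 * d.z_apex + 0.7 * d.z_base))
    )
    n_r = max(4, int(round(r_max / h_coarse)) + 1)

    z_lo, z_hi = d.z_base - refine_margin, d.z_sinus_top

    def h_of_z(z):
        if z_lo - h_coarse < z < z_hi:
            return h_fine
        return h_coarse

    layers = graded_layers(d.z_apex, d.z_out, h_of_z)
    mesh = build_swept_mesh(d.radius_fn, layers, n_r, closed_bottom=True)
    if len(mesh.tets) > max_cells:
        raise RuntimeError(
            f"mesh has {len(mesh.tets)} cells (> {max_cells}); "
            "increase h_coarse"
        )
    zc = mesh.points[mesh.tets].mean(axis=1)[:, 2]
    tags = np.full(len(mesh.tets), VENTRICLE, dtype=np.int32)
    tags[(zc >= d.z_base) & (zc < d.z_ann)] = LVOT
    tags[(zc >= d.z_ann) & (zc < d.z_sinus_top)] = AORTIC_ROOT
    tags[zc >= d.z_sinus_top] = ASCENDING
    mesh.cell_tags = tags
    domain.mesh = mesh
    return mesh


# ---------------------------------------------------------------------------
# displacement extension
# ---------------------------------------------------------------------------


@dataclass
class BoundaryMotion:
    """Time-resolved displacement of every boundary node (domain frame, mm)."""

    node_ids: np.ndarray  # (Nb,)
    frame_times: np.ndarray  # (nt,)
    disp: np.ndarray  # (nt, Nb, 3)
    _spline: CubicSpline = field(default=None, repr=False)  # type: ignore

    def __post_init__(self):
        self._spline = CubicSpline(self.frame_times, self.disp, axis=0)

    def at(self, t: float) -> np.ndarray:
        return self._spline(float(t))


def extend_displacement(
    domain: ComputationalDomain,
    disp_field: DisplacementField,
) -> BoundaryMotion:
    """Extend the endocardial displacement to the whole domain boundary.

    Wall nodes on the imaged LV (below the base plane) take the registered
    displacement directly; the outlet section is held fixed; displacement
    on the templates (basal shoulder, aortic root, ascending aorta) solves
    a Laplace-Beltrami problem on the boundary surface with those Dirichlet
    data, giving a smooth decay from the moving base to the fixed outlet.
    """
    mesh = domain.mesh
    if mesh is None:
        raise ValueError("build_mesh must be called before extend_displacement")
    bfaces = mesh.boundary_faces
    bnodes = np.unique(bfaces)
    pts_dom = mesh.points
    z = pts_dom[:, 2]
    outlet_nodes = mesh.boundary_nodes(OUTLET)
    endo_nodes = bnodes[
        (z[bnodes] <= domain.z_base) & ~np.isin(bnodes, outlet_nodes)
    ]
    dir_nodes = np.concatenate([endo_nodes, outlet_nodes])

    K = surface_stiffness(pts_dom, bfaces)
    # restrict to boundary nodes (interior rows are empty): the extension
    # object works on the full index set; interior nodes are never queried
    ext = HarmonicExtension(
        K + 1.0e-12 * _identity_mask(K.shape[0], bnodes), dir_nodes
    )

    world_endo = domain.to_world(pts_dom[endo_nodes])
    nt = len(disp_field.frame_times)
    disp_all = np.zeros((nt, len(bnodes), 3))
    pos = {n: i for i, n in enumerate(bnodes)}
    sel = np.array([pos[n] for n in dir_nodes])
    for k in range(nt):
        d_world = disp_field.sample(world_endo, k)
        d_dom = domain.vectors_to_domain(d_world)
        dir_vals = np.vstack([d_dom, np.zeros((len(outlet_nodes), 3))])
        full = ext.extend(dir_vals)
        disp_all[k] = full[bnodes]
    return BoundaryMotion(
        node_ids=bnodes,
        frame_times=disp_field.frame_times,
        disp=disp_all,
    )


def _identity_mask(n, nodes):
    """Tiny diagonal on non-surface rows so the factorization is nonsingular."""
    import scipy.sparse as sp

    d = np.ones(n)
    d[nodes] = 0.0
    return sp.diags(d)
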