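"""Structured tetrahedral meshing of swept (tube/chamber) domains.

The simulation domains handled here — an LV cavity continued by an outflow
tract and ascending aorta, or a plain cylindrical pipe — are star-shaped
around a centerline, so they can be meshed by extruding a triangulated disk
along the axis and splitting the resulting wedges into tetrahedra.  The
wedge-to-tet split follows the index-ordering rule of Dompierre et al., which
guarantees that the triangulations of shared quadrilateral faces agree
between neighbouring wedges, hence the mesh is conforming by construction.

Boundary faces are extracted as the faces owned by exactly one tetrahedron
and tagged geometrically (axial end caps vs. lateral wall).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# boundary tags
WALL = 1
OUTLET = 2
INLET = 3

TAG_NAMES = {WALL: "wall", OUTLET: "outlet", INLET: "inlet"}


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with tagged boundary faces and subdomains.

    points : (N, 3) node coordinates [mm]
    tets : (E, 4) connectivity, positively oriented
    boundary_faces : (F, 3) outward-oriented boundary triangles
    boundary_tags : (F,) integer tags (WALL/OUTLET/INLET)
    cell_tags : (E,) integer subdomain tags (0 when untagged)
    """

    points: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray
    boundary_tags: np.ndarray
    cell_tags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cell_tags is None:
            self.cell_tags = np.zeros(len(self.tets), dtype=np.int32)

    # -- metrics -----------------------------------------------------------
    def cell_volumes(self, points: np.ndarray | None = None) -> np.ndarray:
        p = self.points if points is None else points
        t = self.tets
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        d3 = p[t[:, 3]] - p[t[:, 0]]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    def volume(self, points: np.ndarray | None = None) -> float:
        return float(self.cell_volumes(points).sum())

    def face_areas_normals(
        self, faces: np.ndarray, points: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Areas and unit normals of (outward-oriented) triangles."""
        p = self.points if points is None else points
        v = np.cross(
            p[faces[:, 1]] - p[faces[:, 0]], p[faces[:, 2]] - p[faces[:, 0]]
        )
        a2 = np.linalg.norm(v, axis=1)
        return 0.5 * a2, v / np.where(a2 > 0, a2, 1.0)[:, None]

    def boundary_nodes(self, tag: int | None = None) -> np.ndarray:
        faces = (
            self.boundary_faces
            if tag is None
            else self.boundary_faces[self.boundary_tags == tag]
        )
        return np.unique(faces)

    def edge_lengths(self, points: np.ndarray | None = None) -> np.ndarray:
        """Lengths of all tet edges (with repetition across cells)."""
        p = self.points if points is None else points
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        return np.concatenate(
            [
                np.linalg.norm(p[self.tets[:, i]] - p[self.tets[:, j]], axis=1)
                for i, j in pairs
            ]
        )

    def min_jacobian(self, points: np.ndarray | None = None) -> float:
        """Smallest cell volume — positivity certifies a valid ALE state."""
        return float(self.cell_volumes(points).min())


# ---------------------------------------------------------------------------
# disk triangulation
# ---------------------------------------------------------------------------


def disk_topology(n_r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Triangulated unit disk: center node + rings of 6*j nodes.

    Returns (rho, theta, triangles) where rho/theta are polar coordinates of
    the nodes (rho in [0, 1]) and triangles is (T, 3) int.
    """
    if n_r < 1:
        raise ValueError("n_r must be >= 1")
    rho = [0.0]
    theta = [0.0]
    ring_start = [0]
    for j in range(1, n_r + 1):
        ring_start.append(len(rho))
        k = np.arange(6 * j)
        rho.extend(np.full(6 * j, j / n_r))
        theta.extend(2.0 * np.pi * k / (6 * j))
    rho_a = np.asarray(rho)
    theta_a = np.asarray(theta)

    tris: list[tuple[int, int, int]] = []
    # center fan
    s1 = ring_start[1]
    for k in range(6):
        tris.append((0, s1 + k, s1 + (k + 1) % 6))
    # annuli
    for j in range(1, n_r):
        inner = np.arange(ring_start[j], ring_start[j] + 6 * j)
        outer = np.arange(ring_start[j + 1], ring_start[j + 1] + 6 * (j + 1))
        tris.extend(
            _bridge_loops(inner, theta_a[inner], outer, theta_a[outer])
        )
    return rho_a, theta_a, np.asarray(tris, dtype=np.int64)


def _bridge_loops(inner, ang_in, outer, ang_out):
    """Triangulate the annulus between two closed loops by angular merge."""
    ni, no = len(inner), len(outer)
    tris = []
    i = j = 0
    # advance whichever loop has the smaller next angle
    while i < ni or j < no:
        nxt_in = ang_in[(i + 1) % ni] + (2 * np.pi if i + 1 >= ni else 0.0)
        nxt_out = ang_out[(j + 1) % no] + (2 * np.pi if j + 1 >= no else 0.0)
        if j >= no or (i < ni and nxt_in <= nxt_out):
            tris.append((inner[i % ni], outer[j % no], inner[(i + 1) % ni]))
            i += 1
        else:
            tris.append((inner[i % ni], outer[j % no], outer[(j + 1) % no]))
            j += 1
    return tris


# ---------------------------------------------------------------------------
# wedge splitting (Dompierre et al. index-ordering rule)
# ---------------------------------------------------------------------------

_PERMS = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ]
)


def split_wedges(wedges: np.ndarray) -> np.ndarray:
    """Split (W, 6) wedges [bottom (0,1,2), top (3,4,5)] into (3W, 4) tets.

    The diagonal of every quad face runs through its smallest global node
    index, so adjacent wedges triangulate shared faces identically.
    """
    w = np.asarray(wedges, dtype=np.int64)
    pos = np.argmin(w, axis=1)
    v = np.take_along_axis(w, _PERMS[pos], axis=1)
    cond = np.minimum(v[:, 1], v[:, 5]) < np.minimum(v[:, 2], v[:, 4])
    tets = np.empty((len(w), 3, 4), dtype=np.int64)
    a = v[cond]
    tets[cond, 0] = a[:, [0, 1, 2, 5]]
    tets[cond, 1] = a[:, [0, 1, 5, 4]]
    tets[cond, 2] = a[:, [0, 4, 5, 3]]
    b = v[~cond]
    tets[~cond, 0] = b[:, [0, 1, 2, 4]]
    tets[~cond, 1] = b[:, [0, 4, 2, 5]]
    tets[~cond, 2] = b[:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------


def extract_boundary(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boundary faces (count == 1) with their opposite (interior) vertex."""
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    opp_local = np.array([0, 1, 2, 0 + 3])  # vertex not on the face
    faces = tets[:, local].reshape(-1, 3)
    opp = tets[:, opp_local].reshape(-1)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    sel = first[counts == 1]
    return faces[sel], opp[sel]


def _orient_outward(points, faces, opp):
    ctr = points[faces].mean(axis=1)
    n = np.cross(
        points[faces[:, 1]] - points[faces[:, 0]],
        points[faces[:, 2]] - points[faces[:, 0]],
    )
    flip = np.einsum("ij,ij->i", n, ctr - points[opp]) < 0
    out = faces.copy()
    out[flip] = out[flip][:, [0, 2, 1]]
    return out


# ---------------------------------------------------------------------------
# swept-domain builder
# ---------------------------------------------------------------------------


def build_swept_mesh(
    radius_fn,
    z_layers: np.ndarray,
    n_r: int,
    closed_bottom: bool = True,
) -> TetMesh:
    """Extrude a triangulated disk along z into a tet mesh.

    radius_fn(theta, z) gives the cross-section radius at azimuth theta and
    height z; cross-sections are centered on the z axis.  With
    ``closed_bottom`` the first layer degenerates to an apex point (a closed
    chamber); otherwise the bottom cap is a boundary tagged ``INLET``.  The
    top cap is always tagged ``OUTLET``, the lateral surface ``WALL``.
    """
    z_layers = np.asarray(z_layers, dtype=float)
    if len(z_layers) < 2 or np.any(np.diff(z_layers) <= 0):
        raise ValueError("z_layers must be strictly increasing, length >= 2")
    rho, theta, tris = disk_topology(n_r)
    m = len(rho)

    disk_z = z_layers[1:] if closed_bottom else z_layers
    pts = []
    offsets = []
    base = 0
    if closed_bottom:
        pts.append(np.array([[0.0, 0.0, z_layers[0]]]))
        base = 1
    for z in disk_z:
        r = rho * np.asarray(radius_fn(theta, z), dtype=float)
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                    np.full(m, z)]))
        offsets.append(base)
        base += m
    points = np.vstack(pts)

    tet_list = []
    if closed_bottom:
        cone = np.column_stack(
            [np.zeros(len(tris), dtype=np.int64), tris + offsets[0]]
        )
        tet_list.append(cone)
    for o0, o1 in zip(offsets[:-1], offsets[1:]):
        wedges = np.hstack([tris + o0, tris + o1])
        tet_list.append(split_wedges(wedges))
    tets = np.vstack(tet_list)

    # enforce positive orientation
    d1 = points[tets[:, 1]] - points[tets[:, 0]]
    d2 = points[tets[:, 2]] - points[tets[:, 0]]
    d3 = points[tets[:, 3]] - points[tets[:, 0]]
    vol = np.einsum("ij,ij->i", np.cross(d1, d2), d3)
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    if np.any(vol == 0):
        raise RuntimeError("degenerate (zero-volume) cell produced")

    faces, opp = extract_boundary(tets)
    faces = _orient_outward(points, faces, opp)
    zc = points[faces].mean(axis=1)[:, 2]
    tol = 1e-9 + 1e-6 * (z_layers[-1] - z_layers[0])
    tags = np.full(len(faces), WALL, dtype=np.int32)
    tags[np.abs(zc - z_layers[-1]) < tol] = OUTLET
    if not closed_bottom:
        tags[np.abs(zc - z_layers[0]) < tol] = INLET
    return TetMesh(points, tets, faces, tags)


def graded_layers(z0: float, z1: float, h_of_z) -> np.ndarray:
    """Axial layer positions with local spacing h_of_z(z), rescaled to hit z1."""
    zs = [z0]
    while zs[-1] < z1:
        h = float(h_of_z(zs[-1]))
        if h <= 0:
            raise ValueError("layer spacing must be positive")
        zs.append(zs[-1] + h)
    zs = np.asarray(zs)
    zs = z0 + (zs - z0) * (z1 - z0) / (zs[-1] - z0)
    return zs


def box_mesh(extent: tuple[float, float, float],
             n: tuple[int, int, int]) -> TetMesh:
    """Structured box [0,Lx]x[0,Ly]x[0,Lz]; each cube split into 6 tets.

    The whole boundary is tagged WALL except the z = Lz cap (OUTLET).
    Mainly used for verification against closed-form flow fields.
    """
    nx, ny, nz = (int(v) + 1 for v in n)
    xs = [np.linspace(0, extent[i], (nx, ny, nz)[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * ny + j) * nz + k

    kuhn = [
        (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
        (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
    ]
    corners = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
               (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    tets = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(nz - 1):
                ids = [vid(i + a, j + b, k + c) for a, b, c in corners]
                for t in kuhn:
                    tets.append([ids[v] for v in t])
    tets = np.asarray(tets, dtype=np.int64)
    d1 = points[tets[:, 1]] - points[tets[:, 0]]
    d2 = points[tets[:, 2]] - points[tets[:, 0]]
    d3 = points[tets[:, 3]] - points[tets[:, 0]]
    neg = np.einsum("ij,ij->i", np.cross(d1, d2), d3) < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    faces, opp = extract_boundary(tets)
    faces = _orient_outward(points, faces, opp)
    zc = points[faces].mean(axis=1)[:, 2]
    tags = np.full(len(faces), WALL, dtype=np.int32)
    tags[np.abs(zc - extent[2]) < 1e-9] = OUTLET
    return TetMesh(points, tets, faces, tags)


def cylinder_mesh(
    radius: float, length: float, n_r: int, n_z: int
) -> TetMesh:
    """Open circular pipe along z in [0, length]; ends tagged INLET/OUTLET."""
    return build_swept_mesh(
        lambda th, z: np.full_like(th, radius),
        np.linspace(0.0, length, n_z + 1),
        n_r,
        closed_bottom=False,
    )
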