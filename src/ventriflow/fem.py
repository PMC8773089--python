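"""P1 finite-element primitives on tetrahedral and triangle meshes.

Everything is assembled in vectorized numpy and returned as scipy sparse
matrices.  Units follow the rest of the package: coordinates in mm are
converted by the caller where SI is required (the flow solver works in SI).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def grad_basis(points: np.ndarray, tets: np.ndarray):
    """Constant P1 basis gradients and cell volumes.

    Returns (grads (E,4,3), vols (E,)).
    """
    p = points[tets]  # (E,4,3)
    e = p[:, 1:] - p[:, :1]  # (E,3,3) rows: edges from vertex 0
    vol = np.einsum("ij,ij->i", np.cross(e[:, 0], e[:, 1]), e[:, 2]) / 6.0
    inv = np.linalg.inv(e)  # (E,3,3); columns map to gradients of phi_1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:] = inv.transpose(0, 2, 1)
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def scalar_stiffness(points: np.ndarray, tets: np.ndarray) -> sp.csr_matrix:
    """Assemble the P1 Laplacian ∫ grad(phi_i)·grad(phi_j)."""
    g, vol = grad_basis(points, tets)
    ke = np.einsum("eik,ejk,e->eij", g, g, vol)
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    n = points.shape[0]
    return sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


def surface_stiffness(points: np.ndarray, tris: np.ndarray) -> sp.csr_matrix:
    """P1 Laplace-Beltrami stiffness on a triangle surface embedded in 3D."""
    p = points[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    nrm = np.cross(e1, e2)
    a2 = np.linalg.norm(nrm, axis=1)
    a2 = np.where(a2 > 0, a2, 1.0)
    # gradients of the barycentric basis within the triangle plane
    nhat = nrm / a2[:, None]
    g = np.empty((len(tris), 3, 3))
    # edge opposite to vertex i, rotated 90 deg in-plane, / (2A)
    g[:, 0] = np.cross(nhat, p[:, 2] - p[:, 1]) / a2[:, None]
    g[:, 1] = np.cross(nhat, p[:, 0] - p[:, 2]) / a2[:, None]
    g[:, 2] = np.cross(nhat, p[:, 1] - p[:, 0]) / a2[:, None]
    area = 0.5 * a2
    ke = np.einsum("eik,ejk,e->eij", g, g, area)
    rows = np.repeat(tris, 3, axis=1).reshape(-1)
    cols = np.tile(tris, (1, 3)).reshape(-1)
    n = points.shape[0]
    return sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


class HarmonicExtension:
    """Solve Laplace problems with Dirichlet data on a fixed operator.

    Used both for the ALE lift (volume mesh, reference configuration) and
    for spreading endocardial displacement over the remaining boundary
    surface.  The operator is factorized once; each call solves for new
    Dirichlet data (columns = components).
    """

    def __init__(self, K: sp.csr_matrix, dirichlet_nodes: np.ndarray):
        n = K.shape[0]
        self.dir_nodes = np.asarray(dirichlet_nodes, dtype=np.int64)
        mask = np.zeros(n, dtype=bool)
        mask[self.dir_nodes] = True
        self.free = np.flatnonzero(~mask)
        self.n = n
        Kc = K.tocsc()
        self._Kff = Kc[self.free][:, self.free]
        self._Kfd = Kc[self.free][:, self.dir_nodes]
        self._lu = spla.splu(self._Kff.tocsc())

    def extend(self, dirichlet_values: np.ndarray) -> np.ndarray:
        """dirichlet_values: (len(dir_nodes), m) -> full field (n, m)."""
        vals = np.atleast_2d(np.asarray(dirichlet_values, dtype=float))
        if vals.shape[0] != len(self.dir_nodes):
            raise ValueError("Dirichlet data size mismatch")
        out = np.zeros((self.n, vals.shape[1]))
        out[self.dir_nodes] = vals
        if len(self.free):
            rhs = -self._Kfd @ vals
            out[self.free] = self._lu.solve(rhs)
        return out


def apply_dirichlet(rows, cols, data, rhs, dofs, values):
    """Impose strong Dirichlet conditions on COO triplets (in place on rhs).

    All entries in Dirichlet rows are zeroed and replaced by appended unit
    diagonal entries; ``rhs[dofs] = values``.  Returns new triplet arrays.
    """
    ndof = rhs.shape[0]
    mask = np.zeros(ndof, dtype=bool)
    mask[dofs] = True
    keep = ~mask[rows]
    data = np.where(keep, data, 0.0)
    rows = np.concatenate([rows, dofs])
    cols = np.concatenate([cols, dofs])
    data = np.concatenate([data, np.ones(len(dofs))])
    rhs[dofs] = values
    return rows, cols, data
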