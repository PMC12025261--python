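"""Linear (P1) tetrahedral finite-element kernels.

Vectorized assembly of stiffness and mass operators for piecewise-linear
fields on labeled tetrahedral meshes, plus boundary-facet utilities used by
the bidomain solver (no-flux surfaces, interface extraction, flux quadrature).
All operators are assembled with per-element isotropic conductivities.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "tet_volumes",
    "p1_gradients",
    "stiffness_matrix",
    "lumped_mass",
    "consistent_mass",
    "boundary_faces",
    "face_areas_normals",
    "boundary_flux",
]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of each tetrahedron (positive for right-handed tets)."""
    p = nodes[tets]  # (ne, 4, 3)
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    d3 = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", d1, np.cross(d2, d3)) / 6.0


def p1_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Gradients of the four P1 shape functions on each tet.

    Returns (grads, vols) where grads has shape (ne, 4, 3) and vols (ne,).
    Shape-function gradients are constant per element.
    """
    p = nodes[tets]
    v0, v1, v2, v3 = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    # Jacobian columns are edge vectors from vertex 0.
    J = np.stack([v1 - v0, v2 - v0, v3 - v0], axis=-1)  # (ne, 3, 3)
    Jinv = np.linalg.inv(J)  # rows are grad(lambda_i) for i = 1..3
    g = np.empty((tets.shape[0], 4, 3))
    g[:, 1:, :] = Jinv
    g[:, 0, :] = -Jinv.sum(axis=1)  # lambda_0 = 1 - sum of the others
    vols = np.abs(np.linalg.det(J)) / 6.0
    return g, vols


def stiffness_matrix(
    nodes: np.ndarray, tets: np.ndarray, sigma: np.ndarray, n_nodes: int | None = None
) -> sp.csr_matrix:
    """Assemble K[i,j] = sum_e sigma_e * vol_e * grad(phi_i).grad(phi_j).

    ``sigma`` is a per-element scalar conductivity. The matrix is returned on
    the full node numbering (size n_nodes), so sub-assemblies over element
    subsets (heart-only, torso-only) can be summed.
    """
    if n_nodes is None:
        n_nodes = nodes.shape[0]
    g, vols = p1_gradients(nodes, tets)
    ke = np.einsum("eid,ejd->eij", g, g) * (sigma * vols)[:, None, None]
    ii = np.repeat(tets, 4, axis=1).reshape(-1)
    jj = np.tile(tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix((ke.reshape(-1), (ii, jj)), shape=(n_nodes, n_nodes))
    return K.tocsr()


def lumped_mass(nodes: np.ndarray, tets: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Row-sum lumped mass: vol_e/4 to each vertex. Returned as a vector."""
    if n_nodes is None:
        n_nodes = nodes.shape[0]
    vols = np.abs(tet_volumes(nodes, tets))
    m = np.zeros(n_nodes)
    np.add.at(m, tets.reshape(-1), np.repeat(vols / 4.0, 4))
    return m


def consistent_mass(nodes: np.ndarray, tets: np.ndarray, n_nodes: int | None = None) -> sp.csr_matrix:
    if n_nodes is None:
        n_nodes = nodes.shape[0]
    vols = np.abs(tet_volumes(nodes, tets))
    base = (np.ones((4, 4)) + np.eye(4)) / 20.0
    me = base[None, :, :] * vols[:, None, None]
    ii = np.repeat(tets, 4, axis=1).reshape(-1)
    jj = np.tile(tets, (1, 4)).reshape(-1)
    return sp.coo_matrix((me.reshape(-1), (ii, jj)), shape=(n_nodes, n_nodes)).tocsr()


def _faces_of(tets: np.ndarray) -> np.ndarray:
    """All 4 faces of each tet, shape (4*ne, 3), unsorted vertex order."""
    f = np.concatenate(
        [
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 1]],
        ]
    )
    return f


def boundary_faces(tets: np.ndarray):
    """Faces bordering exactly one tet.

    Returns (faces, owner) where faces is (nf, 3) node triples and owner the
    index of the single adjacent tet.
    """
    ne = tets.shape[0]
    f = _faces_of(tets)
    owners = np.tile(np.arange(ne), 4)
    key = np.sort(f, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    ks = key[order]
    first = np.ones(len(ks), dtype=bool)
    first[1:] = np.any(ks[1:] != ks[:-1], axis=1)
    # run lengths
    idx = np.flatnonzero(first)
    counts = np.diff(np.append(idx, len(ks)))
    single = idx[counts == 1]
    sel = order[single]
    return f[sel], owners[sel]


def shared_faces(tets_a: np.ndarray, tets_b: np.ndarray):
    """Faces shared by one tet of set A and one of set B (by node triples)."""
    fa, oa = boundary_faces(tets_a)
    fb, ob = boundary_faces(tets_b)
    ka = np.sort(fa, axis=1)
    kb = np.sort(fb, axis=1)
    da = {tuple(k): i for i, k in enumerate(ka)}
    out_a, out_b = [], []
    for j, k in enumerate(map(tuple, kb)):
        i = da.get(k)
        if i is not None:
            out_a.append(i)
            out_b.append(j)
    return fa[out_a], oa[out_a], ob[out_b]


def face_areas_normals(nodes: np.ndarray, faces: np.ndarray, owner_centroids: np.ndarray):
    """Areas and outward unit normals (pointing away from the owning tet)."""
    p = nodes[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = 0.5 * np.linalg.norm(n, axis=1)
    with np.errstate(invalid="ignore"):
        n = n / (2.0 * areas)[:, None]
    fc = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", n, fc - owner_centroids) < 0
    n[flip] *= -1.0
    return areas, n


def boundary_flux(
    nodes: np.ndarray,
    tets: np.ndarray,
    sigma: np.ndarray,
    field: np.ndarray,
    faces: np.ndarray,
    owner: np.ndarray,
) -> np.ndarray:
    """Per-face normal flux integral of sigma * grad(field) . n (outward)."""
    g, _ = p1_gradients(nodes, tets[owner])
    grads = np.einsum("eid,ei->ed", g, field[tets[owner]])
    cent = nodes[tets[owner]].mean(axis=1)
    areas, normals = face_areas_normals(nodes, faces, cent)
    return sigma[owner] * np.einsum("ed,ed->e", grads, normals) * areas


def uniform_refine(nodes: np.ndarray, tets: np.ndarray):
    """1:8 uniform subdivision of a tet mesh.

    Edge midpoints become new nodes; each tet splits into 4 corner tets and 4
    tets from the interior octahedron. Conforming across shared faces because
    face subdivision depends only on the face's own edge midpoints.
    Returns (new_nodes, new_tets, parent_index).
    """
    edges = np.concatenate(
        [tets[:, [a, b]] for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
    )
    ekey = np.sort(edges, axis=1)
    uniq, inv = np.unique(ekey, axis=0, return_inverse=True)
    mid = nodes[uniq].mean(axis=1)
    n0 = nodes.shape[0]
    new_nodes = np.vstack([nodes, mid])
    ne = tets.shape[0]
    m = inv.reshape(6, ne).T + n0  # midpoint node ids: m01,m02,m03,m12,m13,m23
    v0, v1, v2, v3 = tets.T
    m01, m02, m03, m12, m13, m23 = m.T
    corner = [
        np.stack([v0, m01, m02, m03], 1),
        np.stack([v1, m01, m12, m13], 1),
        np.stack([v2, m02, m12, m23], 1),
        np.stack([v3, m03, m13, m23], 1),
    ]
    # octahedron (m01, m02, m03, m12, m13, m23): split along diagonal m02-m13
    octa = [
        np.stack([m01, m02, m03, m13], 1),
        np.stack([m01, m02, m12, m13], 1),
        np.stack([m02, m03, m13, m23], 1),
        np.stack([m02, m12, m13, m23], 1),
    ]
    new_tets = np.concatenate(corner + octa)
    parent = np.tile(np.arange(ne), 8)
    # restore positive orientation where subdivision flipped it
    vol = tet_volumes(new_nodes, new_tets)
    flip = vol < 0
    if flip.any():
        t = new_tets[flip].copy()
        t[:, [0, 1]] = t[:, [1, 0]]
        new_tets[flip] = t
    return new_nodes, new_tets, parent
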