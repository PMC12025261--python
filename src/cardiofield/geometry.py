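"""Simplified heart-torso geometry generation, labeling and transforms.

The simplified whole heart is built from analytic primitives: three nested
ellipsoidal shells (atria on top, ventricular myocardium and Purkinje shell
below) separated by an insulating gap that is bridged only by two stacked
cylinders (atrioventricular node and His bundle); a sphere flush with the
right atrial wall models the sinoatrial node and a cuboid bar the bundle
branches. The heart is meshed by labeling a feature-aligned tensor-product
background grid (each hexahedron split into six Kuhn tetrahedra) with
inside-tests at tet centroids; the torso is a box-shaped volume conductor
filling everything around (and inside) the heart shells.

Coordinates are right-handed and in meters internally: +x toward the
anatomical left, +y anterior, +z cranial.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import fem

MM = 1e-3

# Subdomain labels. 0 is reserved for "unlabeled" (gap / cavity / outside).
SAN, ATRIA, AVN, HIS, BNL, PKJ, VENTRICLES, TORSO = range(1, 9)
LABEL_NAMES = {
    SAN: "SAN",
    ATRIA: "ATRIA",
    AVN: "AVN",
    HIS: "HIS",
    BNL: "BNL",
    PKJ: "PKJ",
    VENTRICLES: "VENTRICLES",
    TORSO: "TORSO",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}
HEART_LABELS = (SAN, ATRIA, AVN, HIS, BNL, PKJ, VENTRICLES)
# Conduction-system priority used both for CSG label overrides and for
# assigning per-node parameters on subdomain boundaries.
LABEL_PRIORITY = (SAN, AVN, HIS, BNL, PKJ, ATRIA, VENTRICLES)

REFINEMENT_LEVELS = ("normal", "fine", "finer")


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric configurations."""


@dataclass(frozen=True)
class GeometryConfig:
    """Nominal dimensions of the simplified heart and torso (meters).

    Defaults approximate adult human anatomy: a 45x45x65 mm ventricular
    half-ellipsoid with a 10 mm free wall, a 3 mm atrial wall, 2-3 mm
    conduction-system cylinders and a 2 mm atrioventricular insulation gap
    inside a 350x250x500 mm box torso. Everything is configurable; the
    property suite does not depend on the exact numbers.
    """

    # ventricular shells (centered at the local origin, lower half z <= 0)
    ventricular_outer: tuple = (45 * MM, 45 * MM, 65 * MM)
    ventricular_wall: float = 10 * MM
    pkj_thickness: float = 4 * MM

    # atrial shell (centered above the gap)
    atrial_outer: tuple = (50 * MM, 50 * MM, 40 * MM)
    atrial_wall: float = 3 * MM
    atrial_center_z: float = 30 * MM

    # atrioventricular insulation gap: slab 0 < z < gap
    gap: float = 2 * MM

    # conduction system primitives; the AVN column sits on the atrial
    # annulus (where the atrial wall meets the gap plane) and the bundle
    # bar runs from the His stump into the septal Purkinje shell
    avn_center_xy: tuple = (-33 * MM, 0.0)
    avn_radius: float = 4 * MM
    avn_z: tuple = (-4 * MM, 4 * MM)
    # the His bundle is deliberately narrow (~3 mm diameter anatomically);
    # a thick His would load the weak AVN front and block AV conduction
    his_radius: float = 1.5 * MM
    his_z: tuple = (-14 * MM, -4 * MM)
    bnl_x: tuple = (-37 * MM, -29 * MM)
    bnl_y: tuple = (-4 * MM, 4 * MM)
    bnl_z: tuple = (-26 * MM, -14 * MM)
    san_center: tuple = (-46 * MM, 0.0, 40 * MM)
    san_radius: float = 4 * MM
    # Bachmann's bundle stimulus site: anterior interatrial roof
    bb_center: tuple = (8 * MM, 44 * MM, 45 * MM)

    # which primitives to include (the disconnected-chambers variant drops
    # SAN / AVN / HIS so the chambers are electrically isolated shells)
    include_san: bool = True
    include_avn: bool = True
    include_his: bool = True
    include_bnl: bool = True
    include_pkj: bool = True  # False relabels the Purkinje shell as muscle
    # interatrial septum: a bath slab splitting the atrial shell into left
    # and right chambers (used by the disconnected-chambers variant)
    interatrial_septum: bool = False
    septum_x: float = 0.0

    # torso box (centered at the torso origin) and heart placement
    torso_size: tuple = (350 * MM, 250 * MM, 500 * MM)
    heart_offset: tuple = (25 * MM, 35 * MM, 40 * MM)
    rotation_deg: float = 0.0  # counterclockwise in the frontal plane (about +y)

    # background-grid spacings; the conduction column (AVN + His) gets a
    # locally refined band because its low conductivity makes the excitation
    # front sub-millimeter -- coarser grids block AV conduction
    h_heart: float = 5 * MM
    h_torso: float = 40 * MM
    h_conduction: float = 1.5 * MM

    # electrode placement (torso frame)
    precordial_z: float = 30 * MM
    precordial_x: tuple = (-30 * MM, 0.0, 30 * MM, 60 * MM, 95 * MM, 130 * MM)

    def validate(self) -> None:
        av = self.atrial_outer
        vv = self.ventricular_outer
        if self.gap <= 0:
            raise GeometryError("isolation gap must be positive")
        if min(av) <= self.atrial_wall or min(vv) <= self.ventricular_wall:
            raise GeometryError("shell wall exceeds semi-axis (non-nested shells)")
        if min(vv) <= self.ventricular_wall + self.pkj_thickness:
            raise GeometryError("Purkinje shell not strictly inside ventricular shell")
        if self.h_heart <= 0 or self.h_torso <= 0:
            raise GeometryError("mesh spacings must be positive")
        for name in ("ventricular_wall", "pkj_thickness", "atrial_wall",
                     "avn_radius", "his_radius", "san_radius"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")

    def heart_bbox(self):
        """Axis-aligned local-frame bounding box of all heart primitives."""
        av = self.atrial_outer
        vv = self.ventricular_outer
        zc = self.atrial_center_z
        lo = np.array([-max(av[0], vv[0]), -max(av[1], vv[1]), -vv[2]])
        hi = np.array([max(av[0], vv[0]), max(av[1], vv[1]), zc + av[2]])
        return lo, hi


def disconnected_chambers_config(**overrides) -> GeometryConfig:
    """Geometry variant with isolated chambers (no SAN/AVN/His bridge).

    Emulates a heart whose left atrium, right atrium and ventricles are three
    separate plain-myocardium solution domains (as in segmented anatomical
    models), so propagation between chambers exists only through timed
    external stimuli: the conduction-system primitives are removed, the
    Purkinje shell is relabeled as ventricular muscle and an interatrial
    septum slab splits the atrial shell.
    """
    return GeometryConfig(include_san=False, include_avn=False, include_his=False,
                          include_bnl=False, include_pkj=False,
                          interatrial_septum=True, **overrides)


@dataclass
class ElectrodeLayout:
    """Ten standard probes snapped to torso outer-surface nodes."""

    names: list
    positions: dict  # name -> (3,) coordinates (on the outer surface)
    node_ids: dict  # name -> mesh node index
    ground_probe: str = "RL"

    @property
    def ground_node(self) -> int:
        return self.node_ids[self.ground_probe]

    def to_dict(self) -> dict:
        return {
            "ground_probe": self.ground_probe,
            "probes": {n: list(map(float, self.positions[n])) for n in self.names},
            "nodes": {n: int(self.node_ids[n]) for n in self.names},
        }


@dataclass
class HeartTorsoMesh:
    """Labeled tetrahedral mesh of the heart (and optionally the torso)."""

    nodes: np.ndarray  # (nn, 3) meters
    tets: np.ndarray  # (ne, 4) int
    labels: np.ndarray  # (ne,) int subdomain per tet
    refinement_level: str = "normal"
    config: GeometryConfig | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    # -- basic quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def volumes(self) -> np.ndarray:
        if "volumes" not in self._cache:
            self._cache["volumes"] = fem.tet_volumes(self.nodes, self.tets)
        return self._cache["volumes"]

    def subdomain_volume(self, label: int) -> float:
        return float(np.abs(self.volumes()[self.labels == label]).sum())

    @property
    def has_torso(self) -> bool:
        return bool(np.any(self.labels == TORSO))

    def heart_tet_mask(self) -> np.ndarray:
        return np.isin(self.labels, HEART_LABELS)

    def heart_nodes(self) -> np.ndarray:
        """Sorted indices of nodes belonging to at least one heart tet."""
        if "heart_nodes" not in self._cache:
            self._cache["heart_nodes"] = np.unique(self.tets[self.heart_tet_mask()])
        return self._cache["heart_nodes"]

    def node_labels(self) -> np.ndarray:
        """Per-node subdomain label (0 where no heart/torso tet touches).

        Nodes shared between subdomains get the highest-priority adjacent
        label (conduction system overrides working myocardium; heart
        overrides torso).
        """
        if "node_labels" in self._cache:
            return self._cache["node_labels"]
        lab = np.zeros(self.n_nodes, dtype=np.int32)
        order = [TORSO] + list(LABEL_PRIORITY[::-1])  # lowest priority first
        for lb in order:
            sel = self.tets[self.labels == lb]
            lab[np.unique(sel)] = lb
        self._cache["node_labels"] = lab
        return lab

    # -- facets -----------------------------------------------------------
    def outer_facets(self):
        """Triangles on the torso outer surface (or the heart surface if no
        torso), each bordering exactly one tet. Returns (faces, owner)."""
        if "outer" not in self._cache:
            faces, owner = fem.boundary_faces(self.tets)
            self._cache["outer"] = (faces, owner)
        return self._cache["outer"]

    def outer_nodes(self) -> np.ndarray:
        faces, _ = self.outer_facets()
        return np.unique(faces)

    def interface_facets(self):
        """Facets separating heart-labeled tets from TORSO tets.

        Returns (faces, heart_owner, torso_owner) with owners as global tet
        indices.
        """
        if "interface" in self._cache:
            return self._cache["interface"]
        hm = self.heart_tet_mask()
        tm = self.labels == TORSO
        hidx = np.flatnonzero(hm)
        tidx = np.flatnonzero(tm)
        faces, oa, ob = fem.shared_faces(self.tets[hm], self.tets[tm])
        out = (faces, hidx[oa], tidx[ob])
        self._cache["interface"] = out
        return out

    # -- integrity --------------------------------------------------------
    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.tets).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        return h.hexdigest()[:16]

    def validate(self, require_all_heart: bool = True) -> None:
        vols = self.volumes()
        if np.any(vols <= 0):
            raise GeometryError("mesh contains non-positively-oriented tets")
        required = [lb for lb in HEART_LABELS if require_all_heart or lb in self.labels]
        split_atria = bool(self.config and self.config.interatrial_septum)
        for lb in required:
            if not np.any(self.labels == lb):
                raise GeometryError(f"subdomain {LABEL_NAMES[lb]} is empty")
            if lb == ATRIA and split_atria:
                ncomp = _n_components(self.tets[self.labels == lb])
                # rotated grids cannot align the septum plane; erosion there
                # may leave small extra fragments beyond the two chambers
                ok = ncomp == 2 if self.config.rotation_deg == 0.0 else ncomp >= 2
                if not ok:
                    raise GeometryError(
                        f"septated atria should form 2 chambers, found {ncomp}")
            elif not _is_connected(self.tets[self.labels == lb]):
                raise GeometryError(f"subdomain {LABEL_NAMES[lb]} is disconnected")


def _n_components(tets: np.ndarray) -> int:
    """Connected components of the tet set's node graph."""
    if len(tets) == 0:
        return 0
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csgraph

    nodes, inv = np.unique(tets, return_inverse=True)
    t = inv.reshape(tets.shape)
    n = len(nodes)
    ii = np.repeat(t, 4, axis=1).reshape(-1)
    jj = np.tile(t, (1, 4)).reshape(-1)
    adj = sp.coo_matrix((np.ones_like(ii), (ii, jj)), shape=(n, n))
    ncomp, _ = csgraph.connected_components(adj.tocsr(), directed=False)
    return ncomp


def _is_connected(tets: np.ndarray) -> bool:
    """Whether the tet set is face-or-edge-or-vertex connected (node graph)."""
    return _n_components(tets) == 1


def heart_connectivity_components(mesh: HeartTorsoMesh, drop_labels=()) -> int:
    """Connected components of the heart tet graph with some labels deleted.

    Used to verify the insulation property: removing the AVN and His tets must
    split atria and ventricles into separate components.
    """
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csgraph

    keep = mesh.heart_tet_mask() & ~np.isin(mesh.labels, list(drop_labels))
    tets = mesh.tets[keep]
    if len(tets) == 0:
        return 0
    nodes, inv = np.unique(tets, return_inverse=True)
    t = inv.reshape(tets.shape)
    n = len(nodes)
    ii = np.repeat(t, 4, axis=1).reshape(-1)
    jj = np.tile(t, (1, 4)).reshape(-1)
    adj = sp.coo_matrix((np.ones_like(ii), (ii, jj)), shape=(n, n))
    ncomp, comp = csgraph.connected_components(adj.tocsr(), directed=False)
    return ncomp


def chambers_connected(mesh: HeartTorsoMesh, drop_labels=()) -> bool:
    """True if some atrial tet and some ventricular tet share a component."""
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csgraph

    keep = mesh.heart_tet_mask() & ~np.isin(mesh.labels, list(drop_labels))
    tets = mesh.tets[keep]
    labs = mesh.labels[keep]
    if not (np.any(labs == ATRIA) and np.any(labs == VENTRICLES)):
        return False
    nodes, inv = np.unique(tets, return_inverse=True)
    t = inv.reshape(tets.shape)
    n = len(nodes)
    ii = np.repeat(t, 4, axis=1).reshape(-1)
    jj = np.tile(t, (1, 4)).reshape(-1)
    adj = sp.coo_matrix((np.ones_like(ii), (ii, jj)), shape=(n, n))
    _, comp = csgraph.connected_components(adj.tocsr(), directed=False)
    ca = np.unique(comp[inv.reshape(t.shape)[labs == ATRIA].reshape(-1)])
    cv = np.unique(comp[inv.reshape(t.shape)[labs == VENTRICLES].reshape(-1)])
    return bool(np.intersect1d(ca, cv).size)


# ---------------------------------------------------------------------------
# background grid construction
# ---------------------------------------------------------------------------

def _axis(breaks, spacings):
    """1D grid through sorted breakpoints with per-interval target spacing."""
    pts = [breaks[0]]
    for (a, b), h in zip(zip(breaks[:-1], breaks[1:]), spacings):
        n = max(1, int(round((b - a) / h)))
        pts.extend(np.linspace(a, b, n + 1)[1:])
    return np.array(pts)


def _axis_with_band(breaks, h_default, band, h_band):
    """Axis where intervals inside ``band`` use the finer ``h_band``."""
    spacings = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        if band is not None and band[0] <= mid <= band[1]:
            spacings.append(h_band)
        else:
            spacings.append(h_default)
    return _axis(breaks, spacings)


def _insert_feature_breaks(breaks, feats, lo, hi, tol):
    # merge only near-coincident planes; a dropped feature plane leaves thin
    # primitives ragged in the background grid, which can break conduction
    merge = min(tol, 0.3 * MM)
    out = set(float(b) for b in breaks)
    for f in feats:
        f = float(f)
        if lo + merge < f < hi - merge and min(abs(f - b) for b in out) > merge:
            out.add(f)
    return sorted(out)


def _grid_axes(cfg: GeometryConfig, with_torso: bool):
    """Per-axis coordinate arrays: fine inside the heart bbox, coarse outside.

    Axis arrays pass exactly through the gap planes (z = 0 and z = gap) and
    through the bounding planes of the small conduction primitives, so thin
    features are resolved by construction at any spacing.
    """
    lo, hi = cfg.heart_bbox()
    margin = cfg.h_heart  # one fine layer beyond the heart
    lo = lo - margin
    hi = hi + margin
    feats_x = [cfg.avn_center_xy[0] - cfg.avn_radius, cfg.avn_center_xy[0] + cfg.avn_radius,
               cfg.bnl_x[0], cfg.bnl_x[1],
               cfg.san_center[0] - cfg.san_radius, cfg.san_center[0] + cfg.san_radius]
    if cfg.interatrial_septum:
        half = max(1.5 * MM, 0.45 * cfg.h_heart)
        feats_x += [cfg.septum_x - half, cfg.septum_x + half]
    feats_y = [cfg.avn_center_xy[1] - cfg.avn_radius, cfg.avn_center_xy[1] + cfg.avn_radius,
               cfg.bnl_y[0], cfg.bnl_y[1],
               cfg.san_center[1] - cfg.san_radius, cfg.san_center[1] + cfg.san_radius]
    feats_z = [0.0, cfg.gap, cfg.avn_z[0], cfg.avn_z[1], cfg.his_z[0], cfg.his_z[1],
               cfg.bnl_z[0], cfg.bnl_z[1],
               cfg.san_center[2] - cfg.san_radius, cfg.san_center[2] + cfg.san_radius]
    # refined band around the AVN/His column (slow conduction needs sub-h
    # resolution to avoid discrete propagation block)
    bands = [None, None, None]
    if cfg.include_avn or cfg.include_his:
        pad = 1 * MM
        cx, cy = cfg.avn_center_xy
        r = max(cfg.avn_radius, cfg.his_radius)
        bands[0] = (cx - r - pad, cx + r + pad)
        bands[1] = (cy - r - pad, cy + r + pad)
        bands[2] = (cfg.his_z[0] - pad, cfg.avn_z[1] + pad)
        feats_x += list(bands[0])
        feats_y += list(bands[1])
        feats_z += list(bands[2])
    if cfg.rotation_deg != 0.0:
        # rotated features no longer axis-align; fall back to a plain fine grid
        feats_x, feats_y, feats_z = [], [], []
        bands = [None, None, None]
    axes = []
    off = np.asarray(cfg.heart_offset) if with_torso else np.zeros(3)
    for d, feats in zip(range(3), (feats_x, feats_y, feats_z)):
        a, b = lo[d] + off[d], hi[d] + off[d]
        feats = [f + off[d] for f in feats]
        band = None
        if bands[d] is not None:
            band = (bands[d][0] + off[d], bands[d][1] + off[d])
        tol = 0.25 * cfg.h_heart
        if with_torso:
            half = cfg.torso_size[d] / 2.0
            if a < -half or b > half:
                raise GeometryError("heart (with clearance) does not fit inside torso")
            breaks = _insert_feature_breaks([a, b], feats, a, b, tol)
            inner = _axis_with_band(breaks, cfg.h_heart, band, cfg.h_conduction)
            left = _axis([-half, a], [cfg.h_torso])[:-1]
            right = _axis([b, half], [cfg.h_torso])[1:]
            axes.append(np.concatenate([left, inner, right]))
        else:
            breaks = _insert_feature_breaks([a, b], feats, a, b, tol)
            axes.append(_axis_with_band(breaks, cfg.h_heart, band, cfg.h_conduction))
    return axes


_KUHN = [
    (0b000, 0b100, 0b110, 0b111),
    (0b000, 0b100, 0b101, 0b111),
    (0b000, 0b010, 0b110, 0b111),
    (0b000, 0b010, 0b011, 0b111),
    (0b000, 0b001, 0b101, 0b111),
    (0b000, 0b001, 0b011, 0b111),
]


def _tensor_tet_mesh(xs, ys, zs):
    """Kuhn (6-tet) triangulation of a tensor-product hexahedral grid."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.reshape(-1), Y.reshape(-1), Z.reshape(-1)], axis=1)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    i, j, k = i.reshape(-1), j.reshape(-1), k.reshape(-1)
    corners = {}
    for c in range(8):
        di, dj, dk = (c >> 2) & 1, (c >> 1) & 1, c & 1
        corners[c] = nid(i + di, j + dj, k + dk)
    tets = []
    for t in _KUHN:
        tets.append(np.stack([corners[c] for c in t], axis=1))
    tets = np.concatenate(tets)
    # fix orientation: same parity within each Kuhn pattern
    vols = fem.tet_volumes(nodes, tets)
    flip = vols < 0
    if flip.any():
        tt = tets[flip]
        tt[:, [2, 3]] = tt[:, [3, 2]]
        tets[flip] = tt
    return nodes, tets


# ---------------------------------------------------------------------------
# CSG labeling
# ---------------------------------------------------------------------------

def _inside_ellipsoid(p, semi, center=(0.0, 0.0, 0.0)):
    q = (p - np.asarray(center)) / np.asarray(semi)
    return np.einsum("ij,ij->i", q, q) <= 1.0


def label_points(points: np.ndarray, cfg: GeometryConfig) -> np.ndarray:
    """Heart subdomain label for each local-frame point (0 = not heart)."""
    p = np.asarray(points, float)
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    out = np.zeros(len(p), dtype=np.int32)

    vo = cfg.ventricular_outer
    vi = tuple(s - cfg.ventricular_wall for s in vo)
    vp = tuple(s - cfg.ventricular_wall - cfg.pkj_thickness for s in vo)
    lower = z <= 0.0
    in_vo = _inside_ellipsoid(p, vo)
    in_vi = _inside_ellipsoid(p, vi)
    in_vp = _inside_ellipsoid(p, vp)
    out[lower & in_vi & ~in_vp] = PKJ if cfg.include_pkj else VENTRICLES
    out[lower & in_vo & ~in_vi] = VENTRICLES

    ac = (0.0, 0.0, cfg.atrial_center_z)
    ao = cfg.atrial_outer
    ai = tuple(s - cfg.atrial_wall for s in ao)
    upper = z >= cfg.gap
    in_ao = _inside_ellipsoid(p, ao, ac)
    in_ai = _inside_ellipsoid(p, ai, ac)
    out[upper & in_ao & ~in_ai] = ATRIA
    if cfg.interatrial_septum:
        half = max(1.5 * MM, 0.45 * cfg.h_heart)
        out[(out == ATRIA) & (np.abs(x - cfg.septum_x) < half)] = 0

    if cfg.include_bnl:
        in_bnl = (
            (x >= cfg.bnl_x[0]) & (x <= cfg.bnl_x[1])
            & (y >= cfg.bnl_y[0]) & (y <= cfg.bnl_y[1])
            & (z >= cfg.bnl_z[0]) & (z <= cfg.bnl_z[1])
        )
        out[in_bnl] = BNL
    cx, cy = cfg.avn_center_xy
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    if cfg.include_his:
        out[(r2 <= cfg.his_radius**2) & (z >= cfg.his_z[0]) & (z <= cfg.his_z[1])] = HIS
    if cfg.include_avn:
        # below the gap the node column stays inside the ventricular cavity
        # so the only path into the ventricles is through the His bundle
        out[(r2 <= cfg.avn_radius**2) & (z >= cfg.avn_z[0]) & (z <= cfg.avn_z[1])
            & (in_vi | (z >= cfg.gap))] = AVN
    if cfg.include_san:
        sc = np.asarray(cfg.san_center)
        d2 = np.einsum("ij,ij->i", p - sc, p - sc)
        out[(d2 <= cfg.san_radius**2) & upper & in_ao] = SAN
    return out


def _enforce_septum_isolation(tets: np.ndarray, labels: np.ndarray,
                              x_local: np.ndarray, septum_x: float) -> None:
    """Unlabel left-atrial tets sharing nodes with right-atrial tets.

    Needed when the background grid is rotated relative to the septum plane
    and centroid labeling alone leaves the two atria node-connected.
    ``x_local`` holds the heart-frame x coordinate of each tet centroid.
    """
    atr = np.isin(labels, (ATRIA, SAN))
    left = atr & (x_local > septum_x)
    right = atr & (x_local <= septum_x)
    if not (left.any() and right.any()):
        return
    right_nodes = np.zeros(tets.max() + 1, dtype=bool)
    right_nodes[np.unique(tets[right])] = True
    conflict = left & right_nodes[tets].any(axis=1)
    labels[conflict] = 0


def _enforce_gap_isolation(tets: np.ndarray, labels: np.ndarray) -> None:
    """Unlabel atrial tets that share nodes with ventricular-side tets.

    On rotated configurations the background grid no longer aligns with the
    insulation-gap planes, so centroid labeling can place an atrial and a
    ventricular tet on the same node, spuriously bridging the chambers
    intracellularly. Such atrial tets are relabeled as non-heart (bath).
    The AVN deliberately bridges the gap and is untouched.
    """
    lower = np.isin(labels, (VENTRICLES, PKJ, BNL, HIS))
    upper = np.isin(labels, (ATRIA, SAN))
    if not (lower.any() and upper.any()):
        return
    lower_nodes = np.zeros(tets.max() + 1, dtype=bool)
    lower_nodes[np.unique(tets[lower])] = True
    conflict = upper & lower_nodes[tets].any(axis=1)
    labels[conflict] = 0


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    """Rotation about +y (anterior-posterior axis): counterclockwise in the
    frontal plane as seen from the front (+y looking toward -y)."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    # counterclockwise in the x-z plane viewed from +y means x->z rotation
    # with the right-hand rule about -y; viewed from anterior, +x (left) tips
    # toward +z (cranial).
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _torso_to_local(points: np.ndarray, cfg: GeometryConfig) -> np.ndarray:
    q = points - np.asarray(cfg.heart_offset)
    if cfg.rotation_deg != 0.0:
        R = _rotation_matrix(cfg.rotation_deg)
        q = q @ R  # inverse rotation: R^T applied as q @ R
    return q


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def build_simplified_heart(cfg: GeometryConfig | None = None,
                           validate: bool = True) -> HeartTorsoMesh:
    """Generate the simplified whole-heart mesh (no torso).

    All seven heart subdomains are present (unless primitives are disabled in
    the config); the atria and ventricles touch only through the AVN-His
    bridge across the insulation gap.
    """
    cfg = cfg or GeometryConfig()
    cfg.validate()
    xs, ys, zs = _grid_axes(cfg, with_torso=False)
    nodes, tets = _tensor_tet_mesh(xs, ys, zs)
    cent = nodes[tets].mean(axis=1)
    labels = label_points(cent, cfg)
    if cfg.rotation_deg != 0.0:
        _enforce_gap_isolation(tets, labels)
        if cfg.interatrial_septum:
            _enforce_septum_isolation(tets, labels, cent[:, 0], cfg.septum_x)
    keep = labels > 0
    tets, labels = tets[keep], labels[keep]
    used, inv = np.unique(tets, return_inverse=True)
    mesh = HeartTorsoMesh(nodes[used], inv.reshape(tets.shape).astype(np.int64),
                          labels, "normal", cfg)
    if validate:
        required = cfg.include_san and cfg.include_avn and cfg.include_his
        mesh.validate(require_all_heart=required)
    return mesh


def embed_in_torso(heart_or_cfg, cfg: GeometryConfig | None = None,
                   validate: bool = True) -> HeartTorsoMesh:
    """Generate the combined heart-torso mesh.

    The torso is a box volume conductor; every background cell not labeled as
    heart tissue (including the insulation gap and the ventricular cavity,
    which communicate with the surrounding bath) becomes TORSO. The heart and
    torso share nodes, so extracellular/torso potential continuity across the
    interface is automatic.
    """
    if isinstance(heart_or_cfg, HeartTorsoMesh):
        cfg = cfg or heart_or_cfg.config or GeometryConfig()
    else:
        cfg = heart_or_cfg if heart_or_cfg is not None else (cfg or GeometryConfig())
    cfg.validate()
    _check_heart_inside_torso(cfg)
    xs, ys, zs = _grid_axes(cfg, with_torso=True)
    nodes, tets = _tensor_tet_mesh(xs, ys, zs)
    cent_local = _torso_to_local(nodes[tets].mean(axis=1), cfg)
    labels = label_points(cent_local, cfg)
    if cfg.rotation_deg != 0.0:
        _enforce_gap_isolation(tets, labels)
        if cfg.interatrial_septum:
            _enforce_septum_isolation(tets, labels, cent_local[:, 0], cfg.septum_x)
    labels[labels == 0] = TORSO
    mesh = HeartTorsoMesh(nodes, tets.astype(np.int64), labels, "normal", cfg)
    if validate:
        required = cfg.include_san and cfg.include_avn and cfg.include_his
        mesh.validate(require_all_heart=required)
    return mesh


def build_heart_torso(cfg: GeometryConfig | None = None, **kw) -> HeartTorsoMesh:
    """Convenience alias: generate the embedded heart-torso mesh directly."""
    return embed_in_torso(cfg or GeometryConfig(), **kw)


def _check_heart_inside_torso(cfg: GeometryConfig) -> None:
    lo, hi = cfg.heart_bbox()
    clearance = cfg.h_heart
    corners = np.array([[lo[d] if (c >> d) & 1 == 0 else hi[d] for d in range(3)]
                        for c in range(8)])
    if cfg.rotation_deg != 0.0:
        R = _rotation_matrix(cfg.rotation_deg)
        corners = corners @ R.T
    corners = corners + np.asarray(cfg.heart_offset)
    half = np.asarray(cfg.torso_size) / 2.0
    if np.any(np.abs(corners) + clearance > half):
        raise GeometryError("heart is not strictly inside the torso (no clearance)")


def rotate_heart(mesh_or_config, angle_deg: float):
    """Rotate the heart counterclockwise in the frontal plane.

    For a GeometryConfig, returns a new config whose generated heart is
    rotated about the anterior-posterior axis through the heart centroid (the
    torso and electrodes are untouched). For a heart-only mesh, rigidly
    rotates the nodes about the centroid. Embedded meshes must be rotated via
    their config (the conforming torso mesh cannot follow a rigid heart
    motion).
    """
    if not -180.0 <= angle_deg <= 180.0:
        raise GeometryError("rotation angle must be within [-180, 180] degrees")
    if isinstance(mesh_or_config, GeometryConfig):
        cfg = replace(mesh_or_config, rotation_deg=mesh_or_config.rotation_deg + angle_deg)
        _check_heart_inside_torso(cfg)
        return cfg
    mesh = mesh_or_config
    if mesh.has_torso:
        raise GeometryError(
            "embedded meshes are rotated by regenerating from a rotated config"
        )
    R = _rotation_matrix(angle_deg)
    c = mesh.nodes.mean(axis=0)
    nodes = (mesh.nodes - c) @ R.T + c
    return HeartTorsoMesh(nodes, mesh.tets.copy(), mesh.labels.copy(),
                          mesh.refinement_level, mesh.config)


def place_electrodes(mesh: HeartTorsoMesh, cfg: GeometryConfig | None = None) -> ElectrodeLayout:
    """Snap the ten standard probes to torso outer-surface nodes.

    Limb probes sit at the four anterior torso corners (RA upper-right, LA
    upper-left, RL lower-right = ground, LL lower-left; the anatomical right
    is -x). V1-V6 sweep across the anterior chest at ventricular level.
    """
    cfg = cfg or mesh.config or GeometryConfig()
    onodes = mesh.outer_nodes()
    pts = mesh.nodes[onodes]
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    yf = hi[1]  # anterior face
    targets = {
        "RA": (lo[0], yf, hi[2]),
        "LA": (hi[0], yf, hi[2]),
        "RL": (lo[0], yf, lo[2]),
        "LL": (hi[0], yf, lo[2]),
    }
    for i, xv in enumerate(cfg.precordial_x, start=1):
        targets[f"V{i}"] = (xv, yf, cfg.precordial_z)
    names = ["RA", "LA", "RL", "LL", "V1", "V2", "V3", "V4", "V5", "V6"]
    positions, node_ids = {}, {}
    for n in names:
        d = np.linalg.norm(pts - np.asarray(targets[n]), axis=1)
        j = int(onodes[int(np.argmin(d))])
        node_ids[n] = j
        positions[n] = mesh.nodes[j].copy()
    return ElectrodeLayout(names, positions, node_ids, ground_probe="RL")


def refine(mesh: HeartTorsoMesh, level: str) -> HeartTorsoMesh:
    """Uniformly subdivide to the requested refinement level.

    Each step splits every tet 1:8 with inherited labels, so subdomain
    volumes are conserved exactly and the tet count multiplies by eight.
    """
    if level not in REFINEMENT_LEVELS:
        raise GeometryError(f"unknown refinement level {level!r}")
    cur = REFINEMENT_LEVELS.index(mesh.refinement_level)
    tgt = REFINEMENT_LEVELS.index(level)
    if tgt < cur:
        raise GeometryError("cannot coarsen by refinement")
    nodes, tets, labels = mesh.nodes, mesh.tets, mesh.labels
    for _ in range(tgt - cur):
        nodes, tets, parent = fem.uniform_refine(nodes, tets)
        labels = labels[parent]
    return HeartTorsoMesh(nodes, tets, labels, level, mesh.config)


def build_bar_mesh(length: float, width: float, h: float,
                   label: int = VENTRICLES) -> HeartTorsoMesh:
    """Thin-bar mesh (single subdomain) for cable-theory surrogate runs."""
    nx = max(2, int(round(length / h)) + 1)
    nw = max(2, int(round(width / h)) + 1)
    xs = np.linspace(0, length, nx)
    ys = np.linspace(0, width, nw)
    zs = np.linspace(0, width, nw)
    nodes, tets = _tensor_tet_mesh(xs, ys, zs)
    labels = np.full(tets.shape[0], label, dtype=np.int32)
    return HeartTorsoMesh(nodes, tets.astype(np.int64), labels, "normal", None)


def config_to_dict(cfg: GeometryConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def config_from_dict(d: dict) -> GeometryConfig:
    fields = {f.name: f for f in dataclasses.fields(GeometryConfig)}
    kw = {}
    for k, v in d.items():
        if k not in fields:
            raise GeometryError(f"unknown geometry config key {k!r}")
        kw[k] = tuple(v) if isinstance(v, list) else v
    return GeometryConfig(**kw)


def config_hash(cfg: GeometryConfig) -> str:
    s = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(s.encode()).hexdigest()[:16]
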