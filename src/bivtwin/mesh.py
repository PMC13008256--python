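"""Tetrahedral meshes for biventricular and slab geometries.

The meshes carry everything downstream stages need: node positions (cm),
4-node tetrahedral connectivity, named boundary node sets (``lv_endo``,
``rv_endo``, ``epi``, ``base``, ``apex``, ``rv_septum`` on ventricular
meshes; ``endo``/``epi``/``base``/``apex`` face surrogates on slabs),
lumped node volumes, and edge-length statistics.

Generators are fully deterministic: structured hexahedral grids are
subdivided into six tetrahedra per cell (Kuhn subdivision), and for the
ventricular geometry the cells whose centroids fall inside an implicit
truncated-ellipsoid shell description are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Mean unique-edge length of the 6-tet Kuhn subdivision of a unit cube:
# per cube 3 axis edges, 3 face diagonals, 1 body diagonal.
_KUHN_EDGE_FACTOR = (3.0 + 3.0 * np.sqrt(2.0) + np.sqrt(3.0)) / 7.0

# Kuhn subdivision of a hexahedron (vertex order: x fastest, then y, z):
# six tets around the 0-7 diagonal.
_KUHN_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
        [0, 4, 5, 7],
        [0, 5, 1, 7],
    ],
    dtype=np.int64,
)


@dataclass
class Mesh:
    """Tetrahedral volume mesh with tagged boundary node sets.

    Attributes
    ----------
    nodes : (N, 3) float array, positions in cm.
    tets : (M, 4) int array, node indices per tetrahedron.
    surface_tags : mapping of tag name to sorted node-index array.
    """

    nodes: np.ndarray
    tets: np.ndarray
    surface_tags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise ValueError("tetrahedron references a node outside the mesh")
        self._tet_volumes: np.ndarray | None = None
        self._node_volumes: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def tet_volumes(self) -> np.ndarray:
        if self._tet_volumes is None:
            p = self.nodes[self.tets]
            a = p[:, 1] - p[:, 0]
            b = p[:, 2] - p[:, 0]
            c = p[:, 3] - p[:, 0]
            self._tet_volumes = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
        return self._tet_volumes

    @property
    def node_volumes(self) -> np.ndarray:
        """Lumped volume per node in cm^3 (quarter of each incident tet)."""
        if self._node_volumes is None:
            vols = np.zeros(self.n_nodes)
            np.add.at(vols, self.tets.ravel(), np.repeat(self.tet_volumes / 4.0, 4))
            self._node_volumes = vols
        return self._node_volumes

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes.sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        pairs = self.tets[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]].reshape(-1, 2)
        pairs.sort(axis=1)
        return np.unique(pairs, axis=0)

    def edge_length_stats(self) -> dict[str, float]:
        e = self.edges()
        ln = np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)
        # reported in micrometres (positions are cm)
        return {
            "min": float(ln.min() * 1e4),
            "mean": float(ln.mean() * 1e4),
            "max": float(ln.max() * 1e4),
        }

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces belonging to exactly one tetrahedron."""
        faces = self.tets[:, [0, 1, 2, 0, 1, 3, 0, 2, 3, 1, 2, 3]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces())


def _structured_grid(counts: tuple[int, int, int], spacing: tuple[float, float, float],
                     origin: tuple[float, float, float] = (0.0, 0.0, 0.0)):
    nx, ny, nz = counts
    xs = origin[0] + spacing[0] * np.arange(nx + 1)
    ys = origin[1] + spacing[1] * np.arange(ny + 1)
    zs = origin[2] + spacing[2] * np.arange(nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack(
        [
            nid(i, j, k), nid(i + 1, j, k), nid(i, j + 1, k), nid(i + 1, j + 1, k),
            nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i, j + 1, k + 1),
            nid(i + 1, j + 1, k + 1),
        ],
        axis=1,
    )
    return nodes, corners


def _cells_to_tets(corners: np.ndarray) -> np.ndarray:
    return corners[:, _KUHN_TETS].reshape(-1, 4)


def _compact(nodes: np.ndarray, tets: np.ndarray):
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[tets], used


def make_slab_mesh(extent_cm, target_edge_um: float = 1000.0) -> Mesh:
    """Tetrahedral slab with opposing faces tagged as endo/epi surrogates.

    Parameters
    ----------
    extent_cm : length-3 sequence
        Slab extents (x, y, z) in cm.
    target_edge_um : float
        Requested mean edge length in micrometres. The grid spacing is set
        so that the mean unique-edge length of the Kuhn subdivision matches
        it; the realized mean stays within +-20 % of the request.

    The z = 0 face is tagged ``endo`` (and ``lv_endo`` as an alias), the
    z = max face ``epi``; the x = 0 / x = max faces are tagged ``base`` /
    ``apex`` so that both transmural and apicobasal Laplace problems can be
    posed on the slab.
    """
    extent = np.asarray(extent_cm, dtype=float)
    if extent.shape != (3,) or np.any(extent <= 0):
        raise ValueError("extent_cm must be three positive lengths")
    if target_edge_um <= 0:
        raise ValueError("target_edge_um must be positive")

    h = (target_edge_um * 1e-4) / _KUHN_EDGE_FACTOR  # cm
    counts = tuple(max(1, int(round(e / h))) for e in extent)
    spacing = tuple(e / c for e, c in zip(extent, counts))
    nodes, corners = _structured_grid(counts, spacing)
    tets = _cells_to_tets(corners)

    x, y, z = nodes.T
    tol = min(spacing) * 1e-6
    tags = {
        "endo": np.flatnonzero(z <= tol),
        "epi": np.flatnonzero(z >= extent[2] - tol),
        "base": np.flatnonzero(x <= tol),
        "apex": np.flatnonzero(x >= extent[0] - tol),
    }
    tags["lv_endo"] = tags["endo"]
    return Mesh(nodes, tets, tags)


@dataclass
class BivGeometry:
    """Implicit description of an idealized truncated-ellipsoid biventricle.

    The LV is a thick-walled half ellipsoid (truncated at the base plane
    z = 0, apex pointing to -z); the RV is a thinner crescent wrapped
    around the LV free wall obtained from a second, laterally offset
    ellipsoid pair. All lengths in cm.
    """

    lv_endo_radii: tuple[float, float, float] = (1.2, 1.2, 2.2)
    wall_thickness: float = 0.8
    rv_endo_radii: tuple[float, float, float] = (2.3, 1.7, 2.4)
    rv_wall_thickness: float = 0.35
    rv_center: tuple[float, float, float] = (1.0, 0.0, 0.3)

    def lv_epi_radii(self) -> np.ndarray:
        return np.asarray(self.lv_endo_radii) + self.wall_thickness

    def rv_epi_radii(self) -> np.ndarray:
        return np.asarray(self.rv_endo_radii) + self.rv_wall_thickness

    def validate(self) -> None:
        if min(self.lv_endo_radii) <= 0 or self.wall_thickness <= 0:
            raise ValueError("LV radii and wall thickness must be positive")
        if min(self.rv_endo_radii) <= 0 or self.rv_wall_thickness <= 0:
            raise ValueError("RV radii and wall thickness must be positive")
        # the RV cavity must not swallow the LV cavity
        if self.rv_endo_radii[0] + self.rv_center[0] <= self.lv_epi_radii()[0]:
            raise ValueError("RV ellipsoid does not extend beyond the LV epicardium")


def _ell(p: np.ndarray, radii, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Ellipsoid level-set: < 1 inside."""
    q = (p - np.asarray(center)) / np.asarray(radii)
    return np.einsum("ij,ij->i", q, q)


def _repair_well_composed(mask: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Fill voxels until the kept set is well-composed.

    A binary voxel set is well-composed when no 2x2 block in any axis
    plane holds a kept diagonal pair against an empty one, and no 2x2x2
    block holds exactly two kept (or exactly two empty) corner-opposite
    voxels; a well-composed set has a 2-manifold boundary surface. Critical
    configurations are repaired by filling one empty voxel, which only ever
    adds a sliver of volume at stair-step contacts.
    """
    m = mask.copy()
    for _ in range(max_iter):
        changed = False
        # edge-critical 2x2 blocks in the three axis planes
        for ax in range(3):
            a = np.moveaxis(m, ax, 0)
            b00 = a[:, :-1, :-1]
            b01 = a[:, :-1, 1:]
            b10 = a[:, 1:, :-1]
            b11 = a[:, 1:, 1:]
            for d0, d1, o0, o1 in ((b00, b11, b01, b10), (b01, b10, b00, b11)):
                crit = d0 & d1 & ~o0 & ~o1
                if crit.any():
                    o0[crit] = True
                    changed = True
        # corner-critical 2x2x2 blocks
        c = [m[i:m.shape[0] - 1 + i, j:m.shape[1] - 1 + j, k:m.shape[2] - 1 + k]
             for i in range(2) for j in range(2) for k in range(2)]
        total = sum(x.astype(np.int8) for x in c)
        for idx in range(4):  # the four corner-opposite pairs
            jdx = 7 - idx
            pair = c[idx] & c[jdx]
            crit = pair & (total == 2)
            if crit.any():
                c[idx ^ 1][crit] = True
                changed = True
            anti = ~c[idx] & ~c[jdx] & (total == 6)
            if anti.any():
                c[idx][anti] = True
                changed = True
        if not changed:
            return m
    return m


def make_biv_mesh(geometry: BivGeometry | None = None,
                  target_edge_um: float = 2000.0) -> Mesh:
    """Idealized biventricular shell mesh with full surface tagging.

    The solid is the union of the LV shell (between the endocardial and
    epicardial ellipsoids) and the RV shell (between the offset RV
    ellipsoid pair, excluding the LV), truncated at the base plane z = 0.
    Cells of a background grid are kept when their centroid lies inside
    the solid; boundary nodes are then classified against the implicit
    surfaces to populate ``lv_endo``, ``rv_endo``, ``epi``, ``base``,
    ``apex`` and ``rv_septum``.
    """
    geom = geometry or BivGeometry()
    geom.validate()

    lv_epi = geom.lv_epi_radii()
    rv_epi = geom.rv_epi_radii()
    rv_c = np.asarray(geom.rv_center)

    h = (target_edge_um * 1e-4) / _KUHN_EDGE_FACTOR
    lo = np.minimum(-lv_epi, rv_c - rv_epi)
    hi = np.maximum(lv_epi, rv_c + rv_epi)
    lo[2] = min(-lv_epi[2], rv_c[2] - rv_epi[2])
    hi[2] = 0.0
    counts = tuple(max(2, int(np.ceil((b - a) / h))) for a, b in zip(lo, hi))
    spacing = tuple((b - a) / c for a, b, c in zip(lo, hi, counts))
    nodes, corners = _structured_grid(counts, spacing, origin=tuple(lo))

    def inside_solid(p):
        in_lv_shell = (_ell(p, lv_epi) < 1.0) & (_ell(p, geom.lv_endo_radii) >= 1.0)
        in_rv_shell = (
            (_ell(p, rv_epi, rv_c) < 1.0)
            & (_ell(p, geom.rv_endo_radii, rv_c) >= 1.0)
            & (_ell(p, geom.lv_endo_radii) >= 1.0)
        )
        # RV shell only outside the LV epicardium (the septum belongs to LV)
        in_rv_shell &= _ell(p, lv_epi) >= 1.0
        return in_lv_shell | in_rv_shell

    centroids = nodes[corners].mean(axis=1)
    keep = inside_solid(centroids) & (centroids[:, 2] < 0.0)
    keep = _repair_well_composed(keep.reshape(counts)).ravel()
    tets = _cells_to_tets(corners[keep])
    nodes, tets, _ = _compact(nodes, tets)
    if len(tets) == 0:
        raise ValueError("geometry produced an empty mesh (self-intersecting parameters?)")
    mesh = Mesh(nodes, tets)

    bnodes = mesh.boundary_nodes()
    p = nodes[bnodes]
    ztol = spacing[2] * 0.75

    base = p[:, 2] >= -ztol
    # distances (in level-set units) to the candidate surfaces
    ell_lv_endo = _ell(p, geom.lv_endo_radii)
    ell_lv_epi = _ell(p, lv_epi)
    ell_rv_endo = _ell(p, geom.rv_endo_radii, rv_c)
    d_lv_endo = np.abs(ell_lv_endo - 1.0)
    d_rv_endo = np.abs(ell_rv_endo - 1.0)
    # the RV ellipsoid pair only bounds the solid outside the LV epicardium
    rv_side = ell_lv_epi >= 1.0 - 1e-9
    d_epi = np.where(rv_side,
                     np.minimum(np.abs(ell_lv_epi - 1.0),
                                np.abs(_ell(p, rv_epi, rv_c) - 1.0)),
                     np.abs(ell_lv_epi - 1.0))
    d_rv_endo = np.where(rv_side, d_rv_endo, np.inf)

    dist = np.column_stack([d_lv_endo, d_rv_endo, d_epi])
    cls = np.argmin(dist, axis=1)
    # septal RV cavity face: on the LV-epi level set but facing (well
    # inside) the RV endocardial ellipsoid — it belongs to the RV endo
    septal = (ell_rv_endo < 0.98) & (np.abs(ell_lv_epi - 1.0) < 0.2)
    cls[septal] = 1

    tags: dict[str, np.ndarray] = {}
    tags["base"] = np.sort(bnodes[base])
    interior = ~base
    tags["lv_endo"] = np.sort(bnodes[interior & (cls == 0)])
    tags["rv_endo"] = np.sort(bnodes[interior & (cls == 1)])
    tags["epi"] = np.sort(bnodes[interior & (cls == 2)])
    tags["rv_septum"] = np.sort(bnodes[interior & septal])

    zmin = nodes[:, 2].min()
    apex_band = spacing[2] * 1.5
    epi_mask = np.zeros(mesh.n_nodes, bool)
    epi_mask[tags["epi"]] = True
    tags["apex"] = np.flatnonzero(epi_mask & (nodes[:, 2] <= zmin + apex_band))

    for name in ("lv_endo", "rv_endo", "epi", "base", "apex", "rv_septum"):
        if len(tags[name]) == 0:
            raise ValueError(f"surface tag {name!r} is empty; geometry too coarse")
    mesh.surface_tags = tags
    return mesh


def boundary_euler_characteristics(mesh: Mesh) -> list[int]:
    """Euler characteristic V - E + F of each connected boundary component."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    faces = mesh.boundary_faces()
    nodes = np.unique(faces)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[nodes] = np.arange(len(nodes))
    f = remap[faces]
    e = np.sort(f[:, [0, 1, 0, 2, 1, 2]].reshape(-1, 2), axis=1)
    e = np.unique(e, axis=0)
    n = len(nodes)
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    ncomp, lab = connected_components(adj, directed=False)
    chis = []
    for c in range(ncomp):
        vmask = lab == c
        V = int(vmask.sum())
        E = int(vmask[e[:, 0]].sum())
        F = int(vmask[f[:, 0]].sum())
        chis.append(V - E + F)
    return chis
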