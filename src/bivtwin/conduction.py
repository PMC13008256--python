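"""His-Purkinje conduction system: tree construction and PMJ coupling.

The His bundle is a polyline routed along surface geodesics between
anatomical landmarks (atrioventricular node, bifurcation, branch
endpoints). Purkinje networks grow from the branch endpoints as binary
fractal trees constrained to the endocardial surface, then optionally
projected into the subendocardial / intramyocardial shells. Six
architecture variants are supported: ``be`` (baseline endocardial),
``bi`` (baseline intramyocardial), ``rvs`` (+ RV septal junctions),
``ap`` (LV branch ends moved apically), ``ap-e`` (everything flattened
back to the endocardium) and ``mi`` (infarct remodelling: junctions in
the affected zone thinned to 42 % and redistributed 51:36:13 over
subendocardial / intramyocardial / epicardial depths).

Terminals couple to all myocardial nodes within the junction radius;
source-sink metrics (connected %, connections per junction, anterograde
% within a [0, 1.5] ms lead window) summarize the coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from bivtwin.anatomy import ScalarField
from bivtwin.mesh import Mesh

__all__ = [
    "PurkinjeTree",
    "PMJCoupling",
    "PMJMetrics",
    "FractalTreeParams",
    "build_his_bundle",
    "grow_fractal_tree",
    "project_tree_depth",
    "apply_variant",
    "couple_pmjs",
    "pmj_metrics",
    "surface_geodesic",
]

DEPTH_LABELS = ("endocardial", "subendocardial", "intramyocardial", "epicardial")


@dataclass
class PurkinjeTree:
    """1-D branching conduction network.

    ``nodes`` are 3-D positions (cm); ``segments`` 2-node line elements
    oriented parent -> child; ``root`` the His origin; ``terminals`` the
    leaves eligible as Purkinje-muscular junctions. ``branch_id`` tracks
    which growth branch each node belongs to.
    """

    nodes: np.ndarray
    segments: np.ndarray
    root: int = 0
    terminals: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    depth_label: np.ndarray | None = None
    branch_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.segments = np.asarray(self.segments, dtype=np.int64).reshape(-1, 2)
        self.terminals = np.asarray(self.terminals, dtype=np.int64)
        if self.depth_label is None:
            self.depth_label = np.zeros(len(self.nodes), dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def parent_map(self) -> np.ndarray:
        """parent[i] for every node (root gets -1); requires a tree."""
        parent = -np.ones(self.n_nodes, dtype=np.int64)
        for a, b in self.segments:
            parent[b] = a
        parent[self.root] = -1
        return parent

    def is_tree(self) -> bool:
        """Connected and acyclic with a unique root."""
        n = self.n_nodes
        if len(self.segments) != n - 1:
            return False
        adj = coo_matrix((np.ones(len(self.segments)),
                          (self.segments[:, 0], self.segments[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp == 1

    def leaf_nodes(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.segments.ravel(), 1)
        leaves = np.flatnonzero(deg == 1)
        return leaves[leaves != self.root]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.nodes[self.segments[:, 0]]
                              - self.nodes[self.segments[:, 1]], axis=1)


@dataclass
class PMJCoupling:
    """Per-terminal myocardial node sets within the junction radius."""

    terminals: np.ndarray
    node_sets: list[np.ndarray]
    radius_mm: float

    def connected_mask(self) -> np.ndarray:
        return np.array([len(s) > 0 for s in self.node_sets])


@dataclass
class PMJMetrics:
    """Coupling summary: connected %, mean connections per connected
    junction, anterograde-activation %."""

    ncPMJ: float
    cpPMJ: float
    aPMJ: float


def _surface_graph(mesh: Mesh, surface_nodes: np.ndarray):
    """Edge graph restricted to a boundary node set, weighted by length."""
    mask = np.zeros(mesh.n_nodes, bool)
    mask[surface_nodes] = True
    e = mesh.edges()
    keep = mask[e[:, 0]] & mask[e[:, 1]]
    e = e[keep]
    w = np.linalg.norm(mesh.nodes[e[:, 0]] - mesh.nodes[e[:, 1]], axis=1)
    n = mesh.n_nodes
    return coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()


def surface_geodesic(mesh: Mesh, surface_nodes: np.ndarray,
                     start_pos, end_pos, tol_cm: float = 0.5) -> np.ndarray:
    """Shortest path (node-index sequence) along the surface edge graph
    between the surface nodes nearest to two 3-D positions."""
    pts = mesh.nodes[surface_nodes]
    tree = cKDTree(pts)
    d0, i0 = tree.query(np.asarray(start_pos, float))
    d1, i1 = tree.query(np.asarray(end_pos, float))
    if d0 > tol_cm or d1 > tol_cm:
        raise ValueError("landmark lies farther than the tolerance from the surface")
    src, dst = surface_nodes[i0], surface_nodes[i1]
    graph = _surface_graph(mesh, surface_nodes)
    dist, pred = dijkstra(graph, directed=False, indices=src, return_predecessors=True)
    if not np.isfinite(dist[dst]):
        # the restricted patch is fragmented: route over the whole boundary
        allb = mesh.boundary_nodes()
        graph = _surface_graph(mesh, allb)
        dist, pred = dijkstra(graph, directed=False, indices=src,
                              return_predecessors=True)
        if not np.isfinite(dist[dst]):
            raise ValueError("landmarks lie on disconnected surface patches")
    path = [dst]
    while path[-1] != src:
        path.append(pred[path[-1]])
    return np.array(path[::-1], dtype=np.int64)


def build_his_bundle(mesh: Mesh, landmarks: dict[str, np.ndarray],
                     tol_cm: float = 0.5) -> PurkinjeTree:
    """His bundle trunk with three branch terminals.

    ``landmarks`` must provide ``av_node``, ``bifurcation``, and the
    branch endpoints ``lv_anterior``, ``lv_posterior``, ``rv``; the
    trunk runs av_node -> bifurcation, then three geodesic branches are
    routed on the LV (anterior/posterior) and RV endocardial surfaces.
    """
    required = {"av_node", "bifurcation", "lv_anterior", "lv_posterior", "rv"}
    missing = required - set(landmarks)
    if missing:
        raise ValueError(f"missing landmarks: {sorted(missing)}")
    lv_surface = mesh.surface_tags.get("lv_endo", mesh.surface_tags.get("endo"))
    rv_surface = mesh.surface_tags.get("rv_endo", lv_surface)

    nodes: list[np.ndarray] = [np.asarray(landmarks["av_node"], float),
                               np.asarray(landmarks["bifurcation"], float)]
    segments: list[tuple[int, int]] = [(0, 1)]
    branch_ids = [0, 0]
    terminals = []

    def add_branch(surface, endpoint, bid):
        path = surface_geodesic(mesh, surface, nodes[1], endpoint, tol_cm=tol_cm)
        prev = 1
        for nid in path:
            nodes.append(mesh.nodes[nid].copy())
            branch_ids.append(bid)
            segments.append((prev, len(nodes) - 1))
            prev = len(nodes) - 1
        terminals.append(prev)

    add_branch(lv_surface, landmarks["lv_anterior"], 1)
    add_branch(lv_surface, landmarks["lv_posterior"], 2)
    add_branch(rv_surface, landmarks["rv"], 3)
    return PurkinjeTree(np.array(nodes), np.array(segments), root=0,
                        terminals=np.array(terminals, dtype=np.int64),
                        branch_id=np.array(branch_ids, dtype=np.int64))


@dataclass
class FractalTreeParams:
    """Growth parameters of the surface-constrained binary fractal tree.

    Defaults give roughly one junction per 25 mm^2 of endocardium on the
    synthetic ventricles: initial branch length 0.8 cm shrinking by 0.8
    per generation, 35-degree branching, 5 generations, 15 % length
    jitter, 3 linear steps per branch.
    """

    initial_length_cm: float = 0.8
    length_ratio: float = 0.8
    branch_angle_deg: float = 35.0
    generations: int = 5
    length_jitter: float = 0.15
    steps_per_branch: int = 3


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / (np.linalg.norm(axis) or 1.0)
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * (axis @ v) * (1 - np.cos(angle)))


def grow_fractal_tree(mesh: Mesh, surface_nodes: np.ndarray,
                      seeds: np.ndarray, params: FractalTreeParams | None = None,
                      exclusions: np.ndarray | None = None,
                      rng_seed: int = 0,
                      initial_directions: np.ndarray | None = None) -> PurkinjeTree:
    """Binary fractal tree grown on a surface node set.

    Each branch advances ``steps_per_branch`` straight steps in the local
    tangent plane, snapping every step point to the surface; at the end
    of a branch two children rotate +-half the branch angle about the
    local surface normal. Branch length shrinks by ``length_ratio`` per
    generation with per-branch log-uniform jitter from ``rng_seed``.
    Steps that would land inside the exclusion node set terminate the
    branch early; terminals are never inside an exclusion region.
    ``generations`` counts branch levels including the initial branch, so
    0 generations returns the seeds untouched and, with no collisions,
    the segment count is
    ``n_seeds * steps_per_branch * (2**generations - 1)``.
    """
    p = params or FractalTreeParams()
    rng = np.random.default_rng(rng_seed)
    surf = np.asarray(surface_nodes, dtype=np.int64)
    pts = mesh.nodes[surf]
    tree_idx = cKDTree(pts)
    normals = _surface_normals(mesh, surf)
    excl_mask = np.zeros(mesh.n_nodes, bool)
    if exclusions is not None and len(exclusions):
        excl_mask[np.asarray(exclusions, dtype=np.int64)] = True

    seeds = np.atleast_2d(np.asarray(seeds, float))
    nodes: list[np.ndarray] = []
    segments: list[tuple[int, int]] = []
    branch_ids: list[int] = []
    terminals: list[int] = []
    next_branch = 0

    def snap(pos):
        _, i = tree_idx.query(pos)
        return pts[i], normals[i], surf[i]

    def grow_branch(start_idx, direction, gen, bid):
        nonlocal next_branch
        length = (p.initial_length_cm * p.length_ratio ** gen
                  * float(np.exp(rng.uniform(-p.length_jitter, p.length_jitter))))
        step = length / p.steps_per_branch
        cur = start_idx
        pos = nodes[cur]
        d = direction
        for _ in range(p.steps_per_branch):
            target = pos + d * step
            snapped, nrm, mesh_id = snap(target)
            if excl_mask[mesh_id]:
                terminals.append(cur)
                return
            # keep the direction tangent after snapping
            d_new = snapped - pos
            if np.linalg.norm(d_new) > 1e-12:
                d = d_new / np.linalg.norm(d_new)
            nodes.append(snapped)
            branch_ids.append(bid)
            segments.append((cur, len(nodes) - 1))
            cur = len(nodes) - 1
            pos = snapped
        if gen + 1 >= p.generations:
            terminals.append(cur)
            return
        _, nrm, _ = snap(pos)
        half = np.deg2rad(p.branch_angle_deg) / 2.0
        for sign in (+1.0, -1.0):
            child_dir = _rodrigues(d, nrm, sign * half)
            next_branch += 1
            grow_branch(cur, child_dir, gen + 1, next_branch)

    for si, seed in enumerate(seeds):
        snapped, nrm, mesh_id = snap(seed)
        nodes.append(snapped)
        branch_ids.append(next_branch)
        root_idx = len(nodes) - 1
        if si > 0:
            segments.append((0, root_idx))  # stitch extra seeds to the first
        if initial_directions is not None:
            d0 = np.asarray(initial_directions[si], float)
            d0 = d0 / np.linalg.norm(d0)
        else:
            # deterministic tangent direction from the surface frame
            ref = np.array([1.0, 0.0, 0.0])
            if abs(nrm @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            d0 = np.cross(nrm, ref)
            nd0 = np.linalg.norm(d0)
            d0 = d0 / nd0 if nd0 > 1e-12 else np.array([0.0, 0.0, 1.0])
        if p.generations > 0:
            grow_branch(root_idx, d0, 0, branch_ids[root_idx])
        else:
            terminals.append(root_idx)
        next_branch += 1

    seg_arr = (np.array(segments, dtype=np.int64) if segments
               else np.empty((0, 2), dtype=np.int64))
    return PurkinjeTree(np.array(nodes), seg_arr, root=0,
                        terminals=np.array(sorted(set(terminals)), dtype=np.int64),
                        branch_id=np.array(branch_ids, dtype=np.int64))


def _surface_normals(mesh: Mesh, surface_nodes: np.ndarray) -> np.ndarray:
    """Area-weighted outward-ish vertex normals on a boundary node set."""
    all_faces = mesh.boundary_faces()
    mask = np.zeros(mesh.n_nodes, bool)
    mask[surface_nodes] = True
    faces = all_faces[mask[all_faces].all(axis=1)]
    fn = np.cross(mesh.nodes[faces[:, 1]] - mesh.nodes[faces[:, 0]],
                  mesh.nodes[faces[:, 2]] - mesh.nodes[faces[:, 0]])
    acc = np.zeros((mesh.n_nodes, 3))
    for k in range(3):
        np.add.at(acc, faces[:, k], fn)
    # nodes whose faces straddle the tag boundary: use all boundary faces
    degenerate = np.linalg.norm(acc[surface_nodes], axis=1) < 1e-12
    if degenerate.any():
        fn_all = np.cross(mesh.nodes[all_faces[:, 1]] - mesh.nodes[all_faces[:, 0]],
                          mesh.nodes[all_faces[:, 2]] - mesh.nodes[all_faces[:, 0]])
        acc_all = np.zeros((mesh.n_nodes, 3))
        for k in range(3):
            np.add.at(acc_all, all_faces[:, k], fn_all)
        bad = surface_nodes[degenerate]
        acc[bad] = acc_all[bad]
    out = acc[surface_nodes]
    n = np.linalg.norm(out, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return out / n


def project_tree_depth(tree: PurkinjeTree, mesh: Mesh,
                       transmural_coord: ScalarField,
                       intramyocardial_fraction: float = 75.0,
                       transmural_cuts=(0.40, 0.75),
                       rng_seed: int = 0) -> PurkinjeTree:
    """Project a surface tree into the wall.

    All nodes move to the subendocardial shell (the outer half of the
    endocardial layer, transmural coordinate in [c1/2, c1] with c1 the
    endo/mid cut); then a seeded random ``intramyocardial_fraction`` % of
    end branches relocate to the intramyocardial shell (the middle third
    of the midmyocardium). Depth labels are updated accordingly.
    """
    if not 0.0 <= intramyocardial_fraction <= 100.0:
        raise ValueError("intramyocardial_fraction must be in [0, 100]")
    c1, c2 = transmural_cuts
    sub_lo, sub_hi = c1 / 2.0, c1
    mid_third = (c1 + (c2 - c1) / 3.0, c1 + 2.0 * (c2 - c1) / 3.0)

    coord = transmural_coord.values
    new = PurkinjeTree(tree.nodes.copy(), tree.segments.copy(), tree.root,
                       tree.terminals.copy(),
                       depth_label=np.full(tree.n_nodes, 1, dtype=np.int64),
                       branch_id=None if tree.branch_id is None else tree.branch_id.copy())
    _snap_to_shell(new, np.arange(new.n_nodes), mesh, coord, (sub_lo, sub_hi))

    rng = np.random.default_rng(rng_seed)
    terms = new.terminals
    n_move = int(round(len(terms) * intramyocardial_fraction / 100.0))
    move = rng.choice(len(terms), size=n_move, replace=False) if n_move else np.array([], int)
    moved = terms[np.sort(move)]
    if len(moved):
        _snap_to_shell(new, moved, mesh, coord, mid_third)
        new.depth_label[moved] = 2
    return new


def _snap_to_shell(tree: PurkinjeTree, node_ids: np.ndarray, mesh: Mesh,
                   coord: np.ndarray, band: tuple[float, float]) -> None:
    lo, hi = band
    in_band = np.flatnonzero((coord >= lo) & (coord <= hi))
    if len(in_band) == 0:
        mid = (lo + hi) / 2.0
        in_band = np.argsort(np.abs(coord - mid))[:max(1, mesh.n_nodes // 100)]
        warnings.warn("no mesh node inside the requested shell; using nearest band")
    kd = cKDTree(mesh.nodes[in_band])
    _, near = kd.query(tree.nodes[node_ids])
    tree.nodes[node_ids] = mesh.nodes[in_band[near]]


def apply_variant(tree: PurkinjeTree, variant: str, mesh: Mesh,
                  transmural_coord: ScalarField | None = None,
                  apicobasal_coord: ScalarField | None = None,
                  az_mask: np.ndarray | None = None,
                  apical_threshold: float = 0.3,
                  rv_septal_pmj_count: int = 12,
                  mi_retention_pct: float = 42.0,
                  mi_depth_proportions=(51.0, 36.0, 13.0),
                  transmural_cuts=(0.40, 0.75),
                  rng_seed: int = 0) -> PurkinjeTree:
    """Realize one of the six conduction-system architecture variants.

    ``be``: identity (baseline endocardial). ``bi``: identity on an
    already-projected tree (projection itself is ``project_tree_depth``).
    ``rvs``: adds a uniform set of RV-septal junctions stitched to the
    nearest tree node. ``ap``: LV terminals above the apical threshold of
    the apicobasal coordinate relocate to the apical endocardium.
    ``ap-e``: all depth labels flattened to endocardial and nodes snapped
    back to the endocardial surface. ``mi``: affected-zone junctions are
    retained at 42 % per depth layer and redistributed 51:36:13 over
    subendocardial / intramyocardial / epicardial shells.
    """
    rng = np.random.default_rng(rng_seed)
    if variant in ("be", "bi"):
        return tree
    new = PurkinjeTree(tree.nodes.copy(), tree.segments.copy(), tree.root,
                       tree.terminals.copy(), depth_label=tree.depth_label.copy(),
                       branch_id=None if tree.branch_id is None else tree.branch_id.copy())

    if variant == "rvs":
        sept = mesh.surface_tags.get("rv_septum")
        if sept is None or len(sept) == 0:
            raise ValueError("mesh has no rv_septum tag")
        take = rng.choice(len(sept), size=min(rv_septal_pmj_count, len(sept)),
                          replace=False)
        new_pts = mesh.nodes[sept[np.sort(take)]]
        kd = cKDTree(new.nodes)
        _, attach = kd.query(new_pts)
        # each septal junction gets a short penultimate stub (0.8 mm) so its
        # anterograde lead time is governed by the junction, not by a long
        # attachment segment
        nodes_new, segs, term_ids = [], [], []
        idx = new.n_nodes
        for i, a in enumerate(attach):
            direction = new.nodes[a] - new_pts[i]
            nd = np.linalg.norm(direction)
            pen = new_pts[i] + (direction / nd * min(0.08, 0.5 * nd)
                                if nd > 1e-9 else [0.0, 0.0, 0.08])
            nodes_new += [pen, new_pts[i]]
            segs += [(int(a), idx), (idx, idx + 1)]
            term_ids.append(idx + 1)
            idx += 2
        start = new.n_nodes
        new.nodes = np.vstack([new.nodes, np.array(nodes_new)])
        new.segments = np.vstack([new.segments, np.array(segs, dtype=np.int64)])
        n_add = len(nodes_new)
        new.depth_label = np.concatenate([new.depth_label,
                                          np.zeros(n_add, dtype=np.int64)])
        if new.branch_id is not None:
            new.branch_id = np.concatenate([new.branch_id,
                                            -np.ones(n_add, dtype=np.int64)])
        new.terminals = np.concatenate([new.terminals,
                                        np.array(term_ids, dtype=np.int64)])
        return new

    if variant == "ap":
        if apicobasal_coord is None:
            raise ValueError("ap variant needs the apicobasal coordinate")
        ab = apicobasal_coord.values
        kd_all = cKDTree(mesh.nodes)
        _, near = kd_all.query(new.nodes[new.terminals])
        high = new.terminals[ab[near] > apical_threshold]
        apical_nodes = np.flatnonzero(ab <= apical_threshold)
        if len(apical_nodes) == 0:
            raise ValueError("no mesh node below the apical threshold")
        kd = cKDTree(mesh.nodes[apical_nodes])
        _, tgt = kd.query(new.nodes[high])
        new.nodes[high] = mesh.nodes[apical_nodes[tgt]]
        return new

    if variant == "ap-e":
        endo = np.concatenate([mesh.surface_tags.get("lv_endo",
                                                     mesh.surface_tags.get("endo")),
                               mesh.surface_tags.get("rv_endo", np.array([], dtype=np.int64))])
        kd = cKDTree(mesh.nodes[endo])
        _, near = kd.query(new.nodes)
        new.nodes = mesh.nodes[endo[near]].astype(float).copy()
        new.depth_label[:] = 0
        return new

    if variant == "mi":
        if az_mask is None or transmural_coord is None:
            raise ValueError("mi variant needs az_mask and the transmural coordinate")
        az = np.zeros(mesh.n_nodes, bool)
        az[np.asarray(az_mask, dtype=np.int64)] = True
        kd_all = cKDTree(mesh.nodes)
        _, near = kd_all.query(new.nodes[new.terminals])
        in_az = az[near]
        az_terms = new.terminals[in_az]
        if len(az_terms) == 0:
            return new
        # 42 % retention stratified per current depth layer
        keep: list[np.ndarray] = []
        for layer in np.unique(new.depth_label[az_terms]):
            group = az_terms[new.depth_label[az_terms] == layer]
            k = int(round(len(group) * mi_retention_pct / 100.0))
            sel = rng.choice(len(group), size=k, replace=False) if k else np.array([], int)
            keep.append(group[np.sort(sel)])
        kept = np.concatenate(keep) if keep else np.array([], dtype=np.int64)
        removed = np.setdiff1d(az_terms, kept)

        # redistribute the kept AZ junctions 51:36:13 across depth shells
        props = np.asarray(mi_depth_proportions, float)
        counts = _largest_remainder(props, len(kept))
        c1, c2 = transmural_cuts
        bands = [(c1 / 2.0, c1),
                 (c1 + (c2 - c1) / 3.0, c1 + 2.0 * (c2 - c1) / 3.0),
                 (c2, 1.0)]
        depth_codes = (1, 2, 3)
        order = rng.permutation(len(kept))
        start = 0
        coord = transmural_coord.values
        for count, band, code in zip(counts, bands, depth_codes):
            ids = kept[order[start:start + count]]
            start += count
            if len(ids):
                _snap_to_shell(new, ids, mesh, coord, band)
                new.depth_label[ids] = code
        return _prune_terminals(new, removed)

    raise ValueError(f"unknown conduction-system variant {variant!r}")


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by the largest-remainder rule."""
    share = proportions / proportions.sum() * total
    base = np.floor(share).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(share - base))
    base[order[:rem]] += 1
    return base


def _prune_terminals(tree: PurkinjeTree, remove: np.ndarray) -> PurkinjeTree:
    """Drop terminal (leaf) nodes and their dangling segments."""
    if len(remove) == 0:
        return tree
    keep_mask = np.ones(tree.n_nodes, bool)
    keep_mask[remove] = False
    seg_keep = keep_mask[tree.segments].all(axis=1)
    remap = -np.ones(tree.n_nodes, dtype=np.int64)
    remap[keep_mask] = np.arange(keep_mask.sum())
    terminals = tree.terminals[keep_mask[tree.terminals]]
    return PurkinjeTree(tree.nodes[keep_mask], remap[tree.segments[seg_keep]],
                        root=int(remap[tree.root]),
                        terminals=remap[terminals],
                        depth_label=tree.depth_label[keep_mask],
                        branch_id=None if tree.branch_id is None
                        else tree.branch_id[keep_mask])


def couple_pmjs(tree: PurkinjeTree, mesh: Mesh, radius_mm: float) -> PMJCoupling:
    """All mesh nodes within the junction radius of each terminal.

    Spatial-index accelerated; identical to a brute-force Euclidean
    distance check. Terminals with no node in range are retained with an
    empty set (flagged unconnected by the metrics).
    """
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    kd = cKDTree(mesh.nodes)
    r_cm = radius_mm / 10.0
    sets = kd.query_ball_point(tree.nodes[tree.terminals], r_cm)
    node_sets = [np.array(sorted(s), dtype=np.int64) for s in sets]
    return PMJCoupling(tree.terminals.copy(), node_sets, float(radius_mm))


def pmj_metrics(coupling: PMJCoupling, tree: PurkinjeTree,
                cs_at: np.ndarray, myo_at: np.ndarray,
                window_ms: float = 1.5) -> PMJMetrics:
    """Source-sink coupling metrics.

    ``ncPMJ``: % of terminals with at least one coupled myocardial node.
    ``cpPMJ``: mean coupled-node count over connected terminals.
    ``aPMJ``: % of terminals with at least one coupled node whose
    activation lags the terminal's parent (penultimate) conduction-system
    node by a time inside [0, window_ms] — anterograde activation.
    Unactivated sites carry +inf activation times.
    """
    if window_ms < 0:
        raise ValueError("window_ms must be non-negative")
    n = len(coupling.terminals)
    if n == 0:
        return PMJMetrics(0.0, 0.0, 0.0)
    connected = coupling.connected_mask()
    nc = 100.0 * connected.sum() / n
    cp = (float(np.mean([len(s) for s, c in zip(coupling.node_sets, connected) if c]))
          if connected.any() else 0.0)
    parent = tree.parent_map()
    antero = 0
    for term, nodes_set, conn in zip(coupling.terminals, coupling.node_sets, connected):
        if not conn:
            continue
        pen = parent[term]
        if pen < 0:
            continue
        ref = cs_at[pen]
        if not np.isfinite(ref):
            continue
        lag = myo_at[nodes_set] - ref
        if np.any((lag >= 0.0) & (lag <= window_ms)):
            antero += 1
    return PMJMetrics(float(nc), cp, 100.0 * antero / n)
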