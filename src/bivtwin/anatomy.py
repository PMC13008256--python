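"""Anatomical labelling: Laplace layers, infarct zones, interpolation.

Transmural and apicobasal coordinates are harmonic interpolants obtained
by solving the steady-state diffusion (Laplace) equation with Dirichlet
data on tagged surfaces and natural zero-flux conditions elsewhere, the
standard Laplace-Dirichlet labelling construction. Layer labels are then
assigned at volume-weighted quantiles of the coordinate. Infarct zones
(healthy / border / scar) come from full-width-half-maximum thresholding
of a late-enhancement intensity surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve

from bivtwin.mesh import Mesh

__all__ = [
    "ScalarField",
    "RegionLabels",
    "FWHMThresholds",
    "solve_laplace",
    "partition_by_fractions",
    "segment_mi_fwhm",
    "rbf_interpolate",
    "stiffness_matrix",
    "element_gradients",
    "transmural_coordinate",
    "apicobasal_coordinate",
    "label_regions",
]

# default layer fractions (%); transmural endo:mid:epi, apicobasal base:middle:apex
TRANSMURAL_FRACTIONS = (40.0, 35.0, 25.0)
APICOBASAL_FRACTIONS = (48.0, 35.0, 17.0)

TRANSMURAL_NAMES = ("endo", "mid", "epi")
APICOBASAL_NAMES = ("apex", "middle", "base")  # ascending apicobasal coordinate
ZONE_NAMES = ("HZ", "BZ", "SZ")


@dataclass
class ScalarField:
    """One real value per mesh node, with a free-form unit label.

    Values must be finite unless ``allow_undefined`` is set (used by
    activation / repolarization maps, where +inf marks sites that never
    activate or never repolarize).
    """

    values: np.ndarray
    units: str = ""
    allow_undefined: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.allow_undefined and not np.all(np.isfinite(self.values)):
            raise ValueError("scalar field contains non-finite values")


@dataclass
class RegionLabels:
    """Per-node integer labels along each anatomical axis.

    ``transmural``: 0=endo, 1=mid, 2=epi; ``apicobasal``: 0=apex,
    1=middle, 2=base (ascending apicobasal coordinate); ``zone``: 0=HZ,
    1=BZ, 2=SZ. Achieved volume fractions (%) are kept alongside.
    """

    transmural: np.ndarray | None = None
    apicobasal: np.ndarray | None = None
    zone: np.ndarray | None = None
    fractions: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class FWHMThresholds:
    """FWHM border-zone thresholds: scar above ``s_bz_plus`` (half the
    affected-zone maximum), border between ``s_bz_minus`` (remote-tissue
    maximum) and ``s_bz_plus``."""

    s_bz_plus: float
    s_bz_minus: float


def element_gradients(mesh: Mesh) -> np.ndarray:
    """P1 shape-function gradients, shape (n_tets, 4, 3)."""
    p = mesh.nodes[mesh.tets]
    # rows of the inverse Jacobian give gradients of barycentric coords
    J = np.stack([p[:, i] - p[:, 0] for i in (1, 2, 3)], axis=2)  # (M,3,3)
    Jinv = np.linalg.inv(J)
    g = np.empty((mesh.n_tets, 4, 3))
    g[:, 1, :] = Jinv[:, 0, :]
    g[:, 2, :] = Jinv[:, 1, :]
    g[:, 3, :] = Jinv[:, 2, :]
    g[:, 0, :] = -(g[:, 1] + g[:, 2] + g[:, 3])
    return g


def stiffness_matrix(mesh: Mesh, tensors: np.ndarray | None = None) -> csr_matrix:
    """FEM stiffness matrix for div(D grad u); D per element or identity."""
    g = element_gradients(mesh)
    vol = mesh.tet_volumes
    if tensors is None:
        Dg = g
    else:
        Dg = np.einsum("mab,mib->mia", tensors, g)
    K_loc = np.einsum("mia,mja->mij", g, Dg) * vol[:, None, None]
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = coo_matrix((K_loc.ravel(), (rows, cols)), shape=(mesh.n_nodes,) * 2)
    return K.tocsr()


def _resolve_node_set(mesh: Mesh, key) -> np.ndarray:
    if isinstance(key, str):
        try:
            return mesh.surface_tags[key]
        except KeyError:
            raise KeyError(f"mesh has no surface tag {key!r}") from None
    return np.asarray(key, dtype=np.int64)


def solve_laplace(mesh: Mesh, dirichlet_sets: dict) -> ScalarField:
    """Harmonic interpolant with Dirichlet data on named node sets.

    ``dirichlet_sets`` maps surface-tag names (or explicit node-index
    arrays) to boundary values. Untagged boundary gets the natural
    zero-flux condition. The discrete maximum principle bounds the
    solution by the boundary values.
    """
    if len(dirichlet_sets) == 0:
        raise ValueError("at least one Dirichlet set is required")
    bc_nodes, bc_vals = [], []
    for key, value in dirichlet_sets.items():
        ids = _resolve_node_set(mesh, key)
        bc_nodes.append(ids)
        bc_vals.append(np.full(len(ids), float(value)))
    bc_nodes = np.concatenate(bc_nodes)
    bc_vals = np.concatenate(bc_vals)
    if len(bc_nodes) == 0:
        raise ValueError("Dirichlet node sets are empty; system is singular")

    fixed = np.zeros(mesh.n_nodes, bool)
    vals = np.zeros(mesh.n_nodes)
    fixed[bc_nodes] = True
    vals[bc_nodes] = bc_vals

    K = stiffness_matrix(mesh)
    free = ~fixed
    rhs = -K[free][:, fixed] @ vals[fixed]
    sol = np.array(vals)
    if free.any():
        sol[free] = spsolve(K[free][:, free].tocsc(), rhs)
    return ScalarField(sol, units="")


def partition_by_fractions(field: ScalarField | np.ndarray,
                           node_volumes: np.ndarray,
                           fractions) -> tuple[np.ndarray, np.ndarray]:
    """Label nodes into layers at volume-weighted quantiles of a field.

    ``fractions`` are percentages summing to 100, ordered by ascending
    field value. Returns ``(labels, achieved_fractions_pct)``. Ties in
    the field are broken by node index so the partition is deterministic.
    """
    values = field.values if isinstance(field, ScalarField) else np.asarray(field, float)
    vols = np.asarray(node_volumes, dtype=float)
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr <= 0):
        raise ValueError("fractions must be positive")
    if abs(fr.sum() - 100.0) > 1e-9:
        raise ValueError("fractions must sum to 100")
    if len(fr) > 1 and np.ptp(values) == 0:
        raise ValueError("constant field cannot be partitioned into >1 layer")

    order = np.lexsort((np.arange(len(values)), values))
    cum = np.cumsum(vols[order])
    total = cum[-1]
    cuts = np.cumsum(fr)[:-1] / 100.0 * total
    # first index whose cumulative volume exceeds each cut
    split = np.searchsorted(cum, cuts, side="left")
    labels = np.empty(len(values), dtype=np.int64)
    start = 0
    for lab, stop in enumerate(list(split) + [len(values)]):
        labels[order[start:stop]] = lab
        start = stop
    achieved = np.array([vols[labels == lab].sum() for lab in range(len(fr))])
    return labels, achieved / total * 100.0


def segment_mi_fwhm(intensity: ScalarField | np.ndarray,
                    az_mask: np.ndarray,
                    remote_mask: np.ndarray) -> tuple[FWHMThresholds, np.ndarray]:
    """Full-width-half-maximum infarct segmentation.

    Scar = affected-zone nodes brighter than half the affected-zone
    maximum; border = affected-zone nodes between the remote maximum and
    that threshold; everything else healthy. Returns the thresholds and
    per-node zone labels (0=HZ, 1=BZ, 2=SZ).
    """
    values = intensity.values if isinstance(intensity, ScalarField) else np.asarray(intensity, float)
    az = np.asarray(az_mask)
    remote = np.asarray(remote_mask)
    if az.dtype == bool:
        az = np.flatnonzero(az)
    if remote.dtype == bool:
        remote = np.flatnonzero(remote)
    labels = np.zeros(len(values), dtype=np.int64)
    if len(az) == 0:
        warnings.warn("empty affected zone; all nodes labelled healthy")
        return FWHMThresholds(np.nan, np.nan), labels
    if len(remote) == 0 or len(np.intersect1d(az, remote)):
        raise ValueError("remote mask must be non-empty and disjoint from the AZ mask")

    s_plus = 0.5 * values[az].max()
    s_minus = float(values[remote].max())
    az_vals = values[az]
    labels[az[az_vals > s_plus]] = 2
    labels[az[(az_vals >= s_minus) & (az_vals <= s_plus)]] = 1
    return FWHMThresholds(float(s_plus), s_minus), labels


def rbf_interpolate(source_points: np.ndarray,
                    source_values: np.ndarray,
                    targets: np.ndarray,
                    kernel: str = "thin_plate_spline",
                    degree: int | None = None,
                    smoothing: float = 0.0) -> np.ndarray:
    """Radial-basis-function interpolation of scattered point data.

    Exact at the source sites for zero smoothing; thin-plate splines with
    the default linear polynomial tail reproduce affine functions
    exactly. Ill-conditioned systems fall back to a lightly regularized
    solve with a warning.
    """
    pts = np.atleast_2d(np.asarray(source_points, float))
    vals = np.asarray(source_values, float)
    tg = np.atleast_2d(np.asarray(targets, float))
    if len(pts) == 0:
        raise ValueError("at least one source point is required")
    uniq = np.unique(pts, axis=0)
    if len(uniq) != len(pts):
        raise ValueError("duplicate source positions")
    try:
        itp = RBFInterpolator(pts, vals, kernel=kernel, degree=degree,
                              smoothing=smoothing)
        out = itp(tg)
    except np.linalg.LinAlgError:
        # coplanar / collinear sources make the polynomial tail rank
        # deficient (typical for surface-sampled mapping points); fall
        # back to a tail-free kernel, regularizing if still singular
        warnings.warn("RBF system ill-conditioned; falling back to a "
                      "linear kernel without polynomial tail")
        try:
            itp = RBFInterpolator(pts, vals, kernel="linear", degree=-1,
                                  smoothing=smoothing)
            out = itp(tg)
        except np.linalg.LinAlgError:
            itp = RBFInterpolator(pts, vals, kernel="linear", degree=-1,
                                  smoothing=max(smoothing, 1e-8))
            out = itp(tg)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("RBF interpolation produced non-finite values")
    return out


def transmural_coordinate(mesh: Mesh) -> ScalarField:
    """Transmural coordinate in [0, 1] (0 on endocardium, 1 on epicardium).

    Two harmonic solves (LV endo -> epi and RV endo -> epi) are blended by
    taking the pointwise maximum of the two normalized solutions, which
    assigns the septum to the LV problem; on meshes without an ``rv_endo``
    tag a single endo -> epi solve is used.
    """
    if "rv_endo" in mesh.surface_tags and len(mesh.surface_tags["rv_endo"]):
        lv = solve_laplace(mesh, {"lv_endo": 0.0, "rv_endo": 1.0, "epi": 1.0})
        rv = solve_laplace(mesh, {"rv_endo": 0.0, "lv_endo": 1.0, "epi": 1.0})
        return ScalarField(1.0 - np.maximum(1.0 - lv.values, 1.0 - rv.values))
    endo_key = "lv_endo" if "lv_endo" in mesh.surface_tags else "endo"
    return solve_laplace(mesh, {endo_key: 0.0, "epi": 1.0})


def apicobasal_coordinate(mesh: Mesh) -> ScalarField:
    """Apicobasal coordinate in [0, 1] (0 at the apex, 1 at the base)."""
    return solve_laplace(mesh, {"apex": 0.0, "base": 1.0})


def label_regions(mesh: Mesh,
                  transmural_fractions=TRANSMURAL_FRACTIONS,
                  apicobasal_fractions=APICOBASAL_FRACTIONS) -> tuple[RegionLabels, ScalarField, ScalarField]:
    """Convenience: solve both Laplace problems and partition the mesh.

    Transmural layers default to the 40:35:25 endo/mid/epi volume split
    and apicobasal layers to the 48:35:17 base/middle/apex split (the
    apicobasal fractions are given base-first; the coordinate ascends
    apex -> base, so they are applied reversed).
    """
    tm = transmural_coordinate(mesh)
    ab = apicobasal_coordinate(mesh)
    tm_labels, tm_frac = partition_by_fractions(tm, mesh.node_volumes,
                                                transmural_fractions)
    ab_labels, ab_frac = partition_by_fractions(ab, mesh.node_volumes,
                                                list(apicobasal_fractions)[::-1])
    labels = RegionLabels(transmural=tm_labels, apicobasal=ab_labels,
                          fractions={"transmural": tm_frac, "apicobasal": ab_frac})
    return labels, tm, ab
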