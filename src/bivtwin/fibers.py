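"""Myocardial fiber fields: tensor fitting and rule-based construction.

Diffusion tensors are fitted per node from diffusion-weighted signal
attenuation by ordinary least squares in the log domain; the primary
eigenvector gives the local longitudinal fiber axis and the eigenvalue
dispersion gives the fractional anisotropy. Rule-based fiber fields
rotate the local circumferential direction by a helix angle alpha that
varies linearly across the wall between endocardial and epicardial
values, per ventricle, with the septum treated as part of the LV and the
sheet-tilt angle beta fixed at zero (transverse isotropy). The mean
angular deviation between two fiber fields drives a two-stage grid
search that calibrates the rule angles against tensor-derived fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bivtwin.anatomy import ScalarField, element_gradients
from bivtwin.mesh import Mesh
from bivtwin.synthetic import DWSignalSet

__all__ = [
    "TensorField",
    "FiberField",
    "RBMAngles",
    "fit_diffusion_tensor",
    "fractional_anisotropy",
    "principal_fiber_direction",
    "local_wall_basis",
    "rbm_fiber_field",
    "mean_angle_theta",
    "calibrate_rbm_angles",
    "CalibrationTrace",
]


@dataclass
class TensorField:
    """Symmetric 3x3 diffusion tensor per node (mm^2/s), with cached
    descending eigenvalues and matching eigenvectors."""

    tensors: np.ndarray  # (N, 3, 3)
    valid: np.ndarray | None = None  # nodes with usable fits

    def __post_init__(self) -> None:
        D = np.asarray(self.tensors, dtype=float)
        if D.ndim == 2:
            D = D[None]
        if not np.allclose(D, np.transpose(D, (0, 2, 1)), atol=1e-10):
            raise ValueError("tensors must be symmetric to 1e-10")
        self.tensors = D
        if self.valid is None:
            self.valid = np.ones(len(D), bool)
        w, v = np.linalg.eigh(D)  # ascending
        self.eigvals = w[:, ::-1]  # lambda1 >= lambda2 >= lambda3
        self.eigvecs = v[:, :, ::-1]  # column i -> eigval i

    def __len__(self) -> int:
        return len(self.tensors)


@dataclass
class FiberField:
    """Orthonormal fiber frame per element: longitudinal ``f``, sheet
    ``s``, sheet-normal ``n``; the longitudinal direction is sign-free
    (f and -f are the same fiber)."""

    f: np.ndarray
    s: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f = _unitize(np.asarray(self.f, float))
        if self.s is not None:
            self.s = _unitize(np.asarray(self.s, float))
        if self.n is not None:
            self.n = _unitize(np.asarray(self.n, float))

    def __len__(self) -> int:
        return len(self.f)


@dataclass
class RBMAngles:
    """Helix angles (degrees) of the rule-based fiber model.

    The standard field uses +60 / -60 on the endo- / epicardium of both
    ventricles; beta (sheet tilt) is fixed at 0.
    """

    alpha_endo_lv: float = 60.0
    alpha_epi_lv: float = -60.0
    alpha_endo_rv: float = 60.0
    alpha_epi_rv: float = -60.0
    beta: float = 0.0


def _unitize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    return v / n


def fit_diffusion_tensor(dw: DWSignalSet) -> TensorField:
    """Least-squares tensor fit of -ln(S/S0)/b = g^T D g per node.

    Requires at least 6 non-coplanar gradient directions. Nodes with any
    non-positive signal are flagged invalid (their tensor is zero).
    """
    g = dw.gradients
    if len(g) < 6:
        raise ValueError("at least 6 gradient directions are required")
    # design matrix for the 6 unique tensor components
    A = np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    if np.linalg.matrix_rank(A, tol=1e-10) < 6:
        raise ValueError("gradient directions are coplanar/degenerate; tensor not identifiable")
    S = dw.signals
    valid = np.all(S > 0, axis=1)
    Y = np.zeros_like(S)
    Y[valid] = -np.log(S[valid] / dw.s0) / max(dw.b_value, 1e-300)
    coef, *_ = np.linalg.lstsq(A, Y.T, rcond=None)  # (6, N)
    c = coef.T
    D = np.zeros((len(S), 3, 3))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = c[:, 0], c[:, 1], c[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = c[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = c[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = c[:, 5]
    D[~valid] = 0.0
    return TensorField(D, valid=valid)


def fractional_anisotropy(eigvals: np.ndarray) -> np.ndarray:
    """FA = sqrt(((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / (2 (l1^2+l2^2+l3^2))).

    Negative eigenvalues (round-off from a noisy fit) are clipped at 0
    for this computation; the result is clipped into [0, 1]. All-zero
    eigenvalue triples yield NaN (undefined).
    """
    w = np.clip(np.atleast_2d(np.asarray(eigvals, float)), 0.0, None)
    num = ((w[:, 0] - w[:, 1]) ** 2 + (w[:, 1] - w[:, 2]) ** 2
           + (w[:, 2] - w[:, 0]) ** 2)
    den = 2.0 * (w ** 2).sum(axis=1)
    fa = np.full(len(w), np.nan)
    ok = den > 0
    fa[ok] = np.sqrt(num[ok] / den[ok])
    fa = np.clip(fa, 0.0, 1.0)
    return fa if np.asarray(eigvals).ndim > 1 else float(fa[0])


def principal_fiber_direction(tensor: np.ndarray,
                              tol: float = 1e-9) -> tuple[np.ndarray, bool]:
    """Primary eigenvector of a single tensor, sign-normalized so the
    first non-zero component is positive. Returns (direction, ambiguous);
    ambiguous is True when the two leading eigenvalues coincide within
    ``tol`` (the axis is then not unique)."""
    w, v = np.linalg.eigh(np.asarray(tensor, float))
    direction = v[:, -1]
    nz = np.flatnonzero(np.abs(direction) > 1e-12)
    if len(nz) and direction[nz[0]] < 0:
        direction = -direction
    ambiguous = bool(w[-1] - w[-2] <= tol)
    return direction, ambiguous


def local_wall_basis(mesh: Mesh, transmural_coord: ScalarField,
                     apicobasal_coord: ScalarField):
    """Per-element orthonormal wall basis (circumferential, apicobasal,
    transmural) from the gradients of the two Laplace coordinates.

    The transmural direction is the normalized transmural-coordinate
    gradient; the apicobasal direction is the apicobasal gradient
    orthogonalized against it; the circumferential direction completes a
    right-handed frame. Elements with a degenerate gradient inherit the
    nearest valid frame.
    """
    g = element_gradients(mesh)
    e_t = np.einsum("mia,mi->ma", g, transmural_coord.values[mesh.tets])
    e_l = np.einsum("mia,mi->ma", g, apicobasal_coord.values[mesh.tets])
    nt = np.linalg.norm(e_t, axis=1)
    valid = nt > 1e-12
    e_t = _unitize(np.where(valid[:, None], e_t, [1.0, 0.0, 0.0]))
    e_l = e_l - np.einsum("ma,ma->m", e_l, e_t)[:, None] * e_t
    nl = np.linalg.norm(e_l, axis=1)
    valid &= nl > 1e-12
    e_l = _unitize(np.where((nl > 1e-12)[:, None], e_l, [0.0, 0.0, 1.0]))
    e_c = np.cross(e_l, e_t)
    if not valid.all():
        from scipy.spatial import cKDTree
        centers = mesh.nodes[mesh.tets].mean(axis=1)
        if not valid.any():
            raise ValueError("no element has a usable coordinate gradient")
        tree = cKDTree(centers[valid])
        _, near = tree.query(centers[~valid])
        src = np.flatnonzero(valid)[near]
        e_t[~valid], e_l[~valid], e_c[~valid] = e_t[src], e_l[src], e_c[src]
    return e_c, e_l, e_t


def rbm_fiber_field(mesh: Mesh, transmural_coord: ScalarField,
                    apicobasal_coord: ScalarField,
                    ventricle_mask: np.ndarray | None,
                    angles: RBMAngles,
                    basis=None) -> FiberField:
    """Rule-based fiber field on the element frame.

    The helix angle varies linearly with the transmural coordinate from
    alpha_endo (coordinate 0) to alpha_epi (coordinate 1), with separate
    LV and RV angle pairs selected by ``ventricle_mask`` (True = RV;
    None or all-False = everything treated as LV, septum included).
    Fibers lie in the circumferential-apicobasal plane (beta = 0):
    f = cos(alpha) c + sin(alpha) l, sheet = transmural, n = f x s.
    """
    coord = np.clip(transmural_coord.values[mesh.tets].mean(axis=1), 0.0, 1.0)
    e_c, e_l, e_t = basis if basis is not None else local_wall_basis(
        mesh, transmural_coord, apicobasal_coord)
    if ventricle_mask is None:
        rv = np.zeros(mesh.n_tets, bool)
    else:
        rv = np.asarray(ventricle_mask, bool)
        if rv.shape == (mesh.n_nodes,):
            rv = rv[mesh.tets].mean(axis=1) > 0.5
    a_endo = np.where(rv, angles.alpha_endo_rv, angles.alpha_endo_lv)
    a_epi = np.where(rv, angles.alpha_epi_rv, angles.alpha_epi_lv)
    alpha = np.deg2rad(a_endo + (a_epi - a_endo) * coord)
    f = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    s = e_t
    n = np.cross(f, s)
    return FiberField(f, s, n)


def mean_angle_theta(field_a: FiberField | np.ndarray,
                     field_b: FiberField | np.ndarray,
                     fold: bool = True) -> float:
    """Mean angular deviation (degrees) between longitudinal directions.

    With ``fold=True`` (default) the absolute dot product is used, so
    the angle lies in [0, 90] degrees and the metric is invariant to the
    unobservable fiber sign; ``fold=False`` applies the plain arccos.
    Zero-length vectors are skipped.
    """
    a = field_a.f if isinstance(field_a, FiberField) else np.asarray(field_a, float)
    b = field_b.f if isinstance(field_b, FiberField) else np.asarray(field_b, float)
    if a.shape != b.shape:
        raise ValueError("fiber fields must have the same element count")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    if not ok.any():
        raise ValueError("no element with two non-zero fibers")
    dots = np.einsum("ma,ma->m", a[ok], b[ok]) / (na[ok] * nb[ok])
    if fold:
        dots = np.abs(dots)
    ang = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    return float(ang.mean())


@dataclass
class CalibrationTrace:
    """All evaluated candidates of the angle search, stage by stage."""

    stages: list[list[tuple[float, float, float]]] = field(default_factory=list)
    # each entry: (alpha_endo, alpha_epi, theta_bar)

    def n_evaluations(self, stage: int | None = None) -> int:
        if stage is None:
            return sum(len(s) for s in self.stages)
        return len(self.stages[stage])

    def best(self, stage: int) -> tuple[float, float, float]:
        return min(self.stages[stage], key=lambda t: (t[2], abs(t[0]) + abs(t[1]), t[0], t[1]))


# coarse grid [+90, -90) in 10-degree steps: 18 values, 18 x 18 = 324 pairs
COARSE_GRID = tuple(float(a) for a in range(90, -90, -10))


def calibrate_rbm_angles(mesh: Mesh, transmural_coord: ScalarField,
                         apicobasal_coord: ScalarField,
                         ventricle_mask: np.ndarray | None,
                         dw_fibers: FiberField,
                         fold: bool = True) -> tuple[RBMAngles, CalibrationTrace]:
    """Two-stage grid search of the rule angles against reference fibers.

    Stage 1 fixes the LV at (+60, -60) and sweeps both RV angles over the
    coarse [+90, -90) grid in 10-degree steps (324 candidates); stage 2
    refines each RV angle within +-10 degrees in 1-degree steps. Stages 3
    and 4 repeat the sweep for the LV with the RV fixed at its optimum.
    Ties resolve to the smallest-magnitude angle pair (then
    lexicographically) for determinism.
    """
    if len(dw_fibers) != mesh.n_tets:
        raise ValueError("reference fibers must be defined per element")
    basis = local_wall_basis(mesh, transmural_coord, apicobasal_coord)
    trace = CalibrationTrace()

    def evaluate(angles: RBMAngles) -> float:
        f = rbm_fiber_field(mesh, transmural_coord, apicobasal_coord,
                            ventricle_mask, angles, basis=basis)
        return mean_angle_theta(f, dw_fibers, fold=fold)

    def sweep(grid_endo, grid_epi, make_angles) -> tuple[float, float]:
        stage: list[tuple[float, float, float]] = []
        for ae in grid_endo:
            for ap in grid_epi:
                stage.append((float(ae), float(ap), evaluate(make_angles(ae, ap))))
        trace.stages.append(stage)
        best = min(stage, key=lambda t: (t[2], abs(t[0]) + abs(t[1]), t[0], t[1]))
        return best[0], best[1]

    lv = (60.0, -60.0)

    def rv_angles(ae, ap):
        return RBMAngles(lv[0], lv[1], ae, ap)

    rv = sweep(COARSE_GRID, COARSE_GRID, rv_angles)
    rv = sweep(np.arange(rv[0] - 10.0, rv[0] + 10.0 + 0.5),
               np.arange(rv[1] - 10.0, rv[1] + 10.0 + 0.5), rv_angles)

    def lv_angles(ae, ap):
        return RBMAngles(ae, ap, rv[0], rv[1])

    lv = sweep(COARSE_GRID, COARSE_GRID, lv_angles)
    lv = sweep(np.arange(lv[0] - 10.0, lv[0] + 10.0 + 0.5),
               np.arange(lv[1] - 10.0, lv[1] + 10.0 + 0.5), lv_angles)

    return RBMAngles(lv[0], lv[1], rv[0], rv[1]), trace
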