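"""Electrophysiological calibration loops.

Covers the tuning procedures of the modelling pipeline: matching a
target APD90 by bisection on the repolarization-control multiplier (the
inward-rectifier analogue), building regional APD-heterogeneity maps
from transmural x apicobasal labels, fitting the border-zone diffusion
coefficient against a conduction-velocity target on a standardized
strand testbed, pooling per-subject fits into species-level means, the
fractional-anisotropy-driven adjustment of the transverse anisotropy
ratio, and the diffusion-coefficient <-> conductivity unit conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from bivtwin.anatomy import RegionLabels
from bivtwin.fibers import FiberField
from bivtwin.mesh import make_slab_mesh
from bivtwin.propagation import (DiffusionSpec, Stimulus, TwoCurrentModel,
                                 assemble_diffusion, prepace_cell,
                                 run_monodomain)
from bivtwin.signals import activation_map

__all__ = [
    "APDSHSpec",
    "BZCalibration",
    "TABLE_APDSH_TARGETS",
    "tune_apd_control",
    "tune_apd_control_batch",
    "build_apdsh_map",
    "tune_bz_ldc",
    "strand_cv",
    "pool_bz_params",
    "adjust_bz_anisotropy",
    "diffusion_conductivity",
]

# Regional APD90 targets (ms) at a 650 ms cycle length, rows = transmural
# (endo, mid, epi), columns = apicobasal (base, middle, apex); the
# mid-wall middle-height entry is the baseline cell's own duration.
TABLE_APDSH_TARGETS = {
    ("endo", "base"): 213.9, ("endo", "middle"): 222.7, ("endo", "apex"): 218.3,
    ("mid", "base"): 204.8, ("mid", "middle"): 213.2, ("mid", "apex"): 208.9,
    ("epi", "base"): 199.0, ("epi", "middle"): 207.2, ("epi", "apex"): 203.1,
}

TRANSMURAL_KEYS = ("endo", "mid", "epi")
APICOBASAL_KEYS = ("apex", "middle", "base")  # label order 0,1,2


@dataclass
class APDSHSpec:
    """APD spatial-heterogeneity configuration.

    ``mode`` ``b``: uniform (the mid-wall middle-height value); ``t``:
    three transmural values at middle height; ``c``: the full 3 x 3
    transmural x apicobasal table.
    """

    mode: str = "c"
    region_targets: dict = field(default_factory=lambda: dict(TABLE_APDSH_TARGETS))
    cycle_length_ms: float = 650.0

    def regions(self) -> list[tuple[str, str]]:
        if self.mode == "b":
            return [("mid", "middle")]
        if self.mode == "t":
            return [(t, "middle") for t in TRANSMURAL_KEYS]
        if self.mode == "c":
            return [(t, a) for t in TRANSMURAL_KEYS for a in ("base", "middle", "apex")]
        raise ValueError("mode must be 'b', 't' or 'c'")

    def validate(self) -> None:
        for r in self.regions():
            if r not in self.region_targets:
                raise ValueError(f"missing APD target for region {r}")
            if self.region_targets[r] <= 0:
                raise ValueError("APD targets must be positive")


@dataclass
class BZCalibration:
    """Per-subject border-zone fits and their pooled means."""

    per_subject: list[dict]

    def pooled(self) -> tuple[float, float]:
        ldc = float(np.mean([s["fitted_ldc"] for s in self.per_subject]))
        apd = float(np.mean([s["fitted_apd_control"] for s in self.per_subject]))
        return ldc, apd


def tune_apd_control(model: TwoCurrentModel, target_apd90_ms: float,
                     cycle_length_ms: float = 650.0, tol_ms: float = 0.5,
                     bounds: tuple[float, float] = (0.25, 20.0),
                     min_beats: int = 6, max_iter: int = 60):
    """Bisection on the repolarization multiplier to match a target APD90.

    APD90 decreases monotonically in the multiplier, so plain bisection
    on the prepaced steady-state APD90 converges; the default tolerance
    is 0.5 ms. Unattainable targets return the bound reached together
    with the APD90 achieved there (``converged`` False).

    Returns ``(multiplier, achieved_apd90, converged)``.
    """
    lo, hi = bounds

    def apd_at(mult: float) -> float:
        m = replace(model, apd_control=mult)
        _, apd, _ = prepace_cell(m, cycle_length_ms, min_beats=min_beats)
        return float(apd)

    apd_lo, apd_hi = apd_at(lo), apd_at(hi)  # apd_lo is the LONG end
    if target_apd90_ms > apd_lo + tol_ms:
        warnings.warn(f"target {target_apd90_ms} ms exceeds the attainable "
                      f"maximum {apd_lo:.1f} ms; returning the bound")
        return lo, apd_lo, False
    if target_apd90_ms < apd_hi - tol_ms:
        warnings.warn(f"target {target_apd90_ms} ms is below the attainable "
                      f"minimum {apd_hi:.1f} ms; returning the bound")
        return hi, apd_hi, False

    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection on a scale factor
        apd_mid = apd_at(mid)
        if abs(apd_mid - target_apd90_ms) < tol_ms:
            return float(mid), apd_mid, True
        if apd_mid > target_apd90_ms:
            lo = mid
        else:
            hi = mid
    return float(mid), apd_mid, False


def build_apdsh_map(labels: RegionLabels, spec: APDSHSpec,
                    tuned_multipliers: dict) -> np.ndarray:
    """Per-node repolarization-multiplier field from regional labels.

    ``b``: uniform mid-wall middle-height value; ``t``: transmural values
    at middle height (constant across apicobasal labels); ``c``: full
    3 x 3 assignment from the transmural and apicobasal node labels.
    """
    spec.validate()
    for region in spec.regions():
        if region not in tuned_multipliers:
            raise ValueError(f"missing tuned multiplier for region {region}")
    tm = labels.transmural
    if tm is None:
        raise ValueError("transmural labels are required")
    n = len(tm)
    out = np.empty(n)
    if spec.mode == "b":
        out[:] = tuned_multipliers[("mid", "middle")]
        return out
    if spec.mode == "t":
        for code, key in enumerate(TRANSMURAL_KEYS):
            out[tm == code] = tuned_multipliers[(key, "middle")]
        return out
    ab = labels.apicobasal
    if ab is None:
        raise ValueError("apicobasal labels are required for mode 'c'")
    for t_code, t_key in enumerate(TRANSMURAL_KEYS):
        for a_code, a_key in enumerate(APICOBASAL_KEYS):
            out[(tm == t_code) & (ab == a_code)] = tuned_multipliers[(t_key, a_key)]
    return out


def tune_apd_control_batch(model: TwoCurrentModel, targets_ms: np.ndarray,
                           cycle_length_ms: float = 650.0, tol_ms: float = 0.5,
                           bounds: tuple[float, float] = (0.25, 20.0),
                           min_beats: int = 5, max_iter: int = 40):
    """Vectorized bisection matching many APD90 targets at once.

    All targets share the pacing protocol, so one batched prepace per
    iteration serves every still-unconverged target. Returns
    ``(multipliers, achieved, converged)`` arrays.
    """
    targets = np.asarray(targets_ms, float)
    lo = np.full(targets.shape, bounds[0])
    hi = np.full(targets.shape, bounds[1])

    def apd_at(mult):
        m = replace(model, apd_control=np.asarray(mult, float))
        _, apd, _ = prepace_cell(m, cycle_length_ms, min_beats=min_beats)
        return np.atleast_1d(apd)

    apd_lo, apd_hi = apd_at(lo), apd_at(hi)
    attainable = (targets <= apd_lo + tol_ms) & (targets >= apd_hi - tol_ms)
    if not attainable.all():
        warnings.warn(f"{int((~attainable).sum())} target(s) outside the "
                      "attainable APD range; bounds returned for those")
    mid = np.sqrt(lo * hi)
    achieved = np.full(targets.shape, np.nan)
    converged = np.zeros(targets.shape, bool)
    for _ in range(max_iter):
        apd_mid = apd_at(mid)
        achieved = apd_mid
        converged = attainable & (np.abs(apd_mid - targets) < tol_ms)
        if converged[attainable].all():
            break
        too_long = apd_mid > targets
        lo = np.where(~converged & too_long, mid, lo)
        hi = np.where(~converged & ~too_long, mid, hi)
        mid = np.where(converged, mid, np.sqrt(lo * hi))
    mid = np.where(attainable, mid, np.where(targets > apd_lo, bounds[0], bounds[1]))
    achieved = np.where(attainable, achieved,
                        np.where(targets > apd_lo, apd_lo, apd_hi))
    return mid, achieved, converged


@dataclass
class _StrandCache:
    mesh: object = None
    edge_um: float = 0.0


_strand_cache = _StrandCache()


def strand_cv(model: TwoCurrentModel, ldc: float,
              transverse_ratio: float = 0.25,
              length_cm: float = 2.0, edge_um: float = 500.0,
              state=None, duration_ms: float | None = None,
              expected_cv_cm_s: float | None = None) -> float:
    """Planar conduction velocity (cm/s) on a standardized 1-D strand.

    A thin 3-D strand paced from one end; velocity is the slope of a
    linear fit of position on activation time over the central half of
    the strand (free of stimulus and boundary effects).
    """
    global _strand_cache
    if _strand_cache.mesh is None or _strand_cache.edge_um != edge_um:
        _strand_cache.mesh = make_slab_mesh((length_cm, 0.1, 0.1), edge_um)
        _strand_cache.edge_um = edge_um
    mesh = _strand_cache.mesh
    fibers = FiberField(np.tile([1.0, 0.0, 0.0], (mesh.n_tets, 1)))
    spec = DiffusionSpec(ldc={0: ldc}, transverse_ratio={0: transverse_ratio})
    op = assemble_diffusion(mesh, fibers, spec)
    if state is None:
        state, _, _ = prepace_cell(model, min_beats=4)
    if duration_ms is None:
        # transit time at the expected velocity plus margin
        cv_guess = expected_cv_cm_s or (
            72.0 * np.sqrt(ldc / 0.0013)
            * np.sqrt(float(np.mean(model.excitability_control))))
        duration_ms = min(250.0, length_cm / max(cv_guess, 5.0) * 1000.0 * 1.4 + 15.0)
    hist = run_monodomain(mesh, op, model, duration_ms,
                          [Stimulus(mesh.surface_tags["base"], 1.0)],
                          initial_state=state)
    at = activation_map(hist).values
    x = mesh.nodes[:, 0]
    sel = (x > length_cm * 0.25) & (x < length_cm * 0.75) & np.isfinite(at)
    if sel.sum() < 10 or np.ptp(at[sel]) <= 0:
        return 0.0  # propagation failed
    slope = np.polyfit(at[sel], x[sel], 1)[0]  # cm/ms
    return float(slope * 1000.0)


def tune_bz_ldc(target_cv_cm_s: float, model: TwoCurrentModel | None = None,
                excitability: float = 0.38, tol_rel: float = 0.05,
                bounds: tuple[float, float] = (5e-5, 5e-3),
                edge_um: float = 500.0, max_iter: int = 40):
    """Fit the border-zone diffusion coefficient to a CV target.

    The testbed is a 2 cm strand with the border-zone cell (excitability
    multiplier 0.38 of healthy). CV grows monotonically with the
    diffusion coefficient, so bisection in log space converges; targets
    below the propagation-failure velocity return the failing bound.

    Returns ``(ldc, achieved_cv, converged)``.
    """
    if target_cv_cm_s <= 0:
        raise ValueError("target CV must be positive")
    base = model or TwoCurrentModel()
    bz_model = replace(base, excitability_control=excitability)
    state, _, _ = prepace_cell(bz_model, min_beats=4)
    lo, hi = bounds

    cv_lo = strand_cv(bz_model, lo, state=state, edge_um=edge_um)
    cv_hi = strand_cv(bz_model, hi, state=state, edge_um=edge_um)
    if target_cv_cm_s <= cv_lo:
        warnings.warn("target CV at/below the lower search bound")
        return lo, cv_lo, False
    if target_cv_cm_s >= cv_hi:
        warnings.warn("target CV above the upper search bound")
        return hi, cv_hi, False
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))
        cv = strand_cv(bz_model, mid, state=state, edge_um=edge_um,
                       expected_cv_cm_s=target_cv_cm_s)
        if cv > 0 and abs(cv - target_cv_cm_s) / target_cv_cm_s < tol_rel:
            return mid, cv, True
        if cv < target_cv_cm_s:
            lo = mid
        else:
            hi = mid
    return mid, cv, False


def pool_bz_params(per_subject: list[tuple[float, float]]) -> tuple[float, float]:
    """Arithmetic means of per-subject (diffusion coefficient, APD
    multiplier %) pairs — the species-level border-zone parameters."""
    if len(per_subject) == 0:
        raise ValueError("at least one subject is required")
    arr = np.asarray(per_subject, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def adjust_bz_anisotropy(fa_hz: float, fa_az: float,
                         baseline_ratio: float = 0.25) -> tuple[float, float]:
    """Anisotropy-ratio update from the fractional-anisotropy decrease.

    The relative FA decrease from healthy to affected tissue,
    pct = (FA_hz - FA_az)/FA_hz, scales the transverse-to-longitudinal
    ratio: new = baseline * (1 + pct). Returns ``(pct, new_ratio)``
    (pct as a fraction, e.g. 0.38). An affected FA above the healthy one
    yields a negative pct with a warning.
    """
    if not (0 <= fa_hz <= 1 and 0 <= fa_az <= 1):
        raise ValueError("FA values must lie in [0, 1]")
    if fa_hz == 0:
        raise ValueError("healthy FA must be positive")
    pct = (fa_hz - fa_az) / fa_hz
    if pct < 0:
        warnings.warn("affected-zone FA exceeds healthy FA; ratio decreases")
    return float(pct), float(baseline_ratio * (1.0 + pct))


def diffusion_conductivity(d_cm2_ms: float, chi_cm_inv: float = 1000.0,
                           cm_uF_cm2: float = 1.0) -> float:
    """Convert a diffusion coefficient to monodomain conductivity (S/m).

    sigma = D * chi * C_m; with D in cm^2/ms, chi in 1/cm and C_m in
    uF/cm^2 the product is in (uF/(ms cm)) = S/cm * 1e-3, i.e.
    sigma[S/m] = D * chi * C_m * 0.1. The healthy 0.0013 cm^2/ms maps to
    0.13 S/m and the conduction-system 0.013 to 1.3 S/m.
    """
    if d_cm2_ms < 0 or chi_cm_inv <= 0 or cm_uF_cm2 <= 0:
        raise ValueError("negative diffusion or non-positive chi / C_m")
    # uF/cm^2 * 1/cm * cm^2/ms = uF/(cm*ms) = 1e-6 F / (1e-2 m * 1e-3 s)
    # = 0.1 S/m per unit product
    return d_cm2_ms * chi_cm_inv * cm_uF_cm2 * 0.1
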