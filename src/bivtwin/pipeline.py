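"""End-to-end experiment orchestration.

``run_experiment`` chains the whole desk-scale workflow from a single
config: synthesize the anatomy, label layers and infarct zones, build
the fiber field, construct and couple the conduction system, calibrate
regional repolarization, integrate the monodomain model for the
requested number of cycles, and analyze the last cycle (activation,
repolarization and velocity maps, pseudo-ECG, junction metrics). Every
stage's artifact is persisted and a JSON report with a config hash makes
runs reproducible.

``pmj_radius_sweep`` reruns coupling + simulation for a list of junction
radii on a compact slab testbed, tabulating the source-sink metrics
(connected %, connections per junction, anterograde %).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bivtwin import anatomy, conduction, fibers, signals, synthetic, vtuio
from bivtwin.calibration import (APDSHSpec, build_apdsh_map,
                                 tune_apd_control_batch)
from bivtwin.conduction import FractalTreeParams, PurkinjeTree
from bivtwin.mesh import Mesh, make_biv_mesh, make_slab_mesh
from bivtwin.propagation import (DiffusionSpec, Stimulus, TwoCurrentModel,
                                 assemble_diffusion, prepace_cell,
                                 run_monodomain)

__all__ = ["ExperimentConfig", "run_experiment", "pmj_radius_sweep",
           "build_conduction_system", "merge_trees", "slab_pmj_testbed"]

SCENARIOS = ("healthy", "mi-lad-like", "mi-lcx-like")
CS_VARIANTS = ("be", "bi", "rvs", "ap", "ap-e", "mi")


@dataclass
class ExperimentConfig:
    """Single-run configuration (the factor combinations of the study's
    simulation groups, at synthetic scale)."""

    scenario: str = "healthy"
    cs_variant: str = "ap"
    apdsh_mode: str = "c"
    fiber_source: str = "s-rbm"  # or "dw-calibrated"
    cycle_length_ms: float = 769.0
    n_cycles: int = 3
    seed: int = 1
    target_edge_um: float = 3000.0
    pmj_radius_mm: float = 0.5
    bz_apd_control: float = 0.29
    bz_excitability: float = 0.38
    bz_ldc: float = 0.000882
    output_dir: str = "bivtwin_run"

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.cs_variant not in CS_VARIANTS:
            raise ValueError(f"cs_variant must be one of {CS_VARIANTS}")
        if self.cs_variant == "mi" and self.scenario == "healthy":
            raise ValueError("the mi conduction-system variant requires an "
                             "infarct scenario")
        if self.cycle_length_ms not in (769.0, 898.0, 1000.0):
            raise ValueError("cycle length must be one of 769, 898 or 1000 ms")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True)
                              .encode()).hexdigest()[:16]


def _auto_landmarks(mesh: Mesh) -> dict[str, np.ndarray]:
    """Heuristic His-bundle landmarks from the surface tags."""
    lv = mesh.nodes[mesh.surface_tags["lv_endo"]]
    rv = mesh.nodes[mesh.surface_tags["rv_endo"]]
    zspan = mesh.nodes[:, 2]
    z_base, z_apex = zspan.max(), zspan.min()
    septal = lv[lv[:, 0] > np.quantile(lv[:, 0], 0.7)]
    if len(septal) == 0:
        septal = lv
    top = septal[np.argmax(septal[:, 2])]
    mid_z = 0.3 * z_base + 0.7 * z_apex
    return {
        "av_node": top,
        "bifurcation": septal[np.argmin(np.abs(septal[:, 2] - 0.8 * z_base
                                               - 0.2 * z_apex))],
        "lv_anterior": lv[np.argmin(np.linalg.norm(
            lv - [lv[:, 0].min(), lv[:, 1].max(), mid_z], axis=1))],
        "lv_posterior": lv[np.argmin(np.linalg.norm(
            lv - [lv[:, 0].min(), lv[:, 1].min(), mid_z], axis=1))],
        "rv": rv[np.argmin(np.linalg.norm(
            rv - [rv[:, 0].max(), rv[:, 1].max(), 0.6 * z_base + 0.4 * z_apex],
            axis=1))],
    }


def merge_trees(trunk: PurkinjeTree,
                attached: list[tuple[int, PurkinjeTree]]) -> PurkinjeTree:
    """Graft subtrees onto trunk nodes (trunk terminal -> subtree root)."""
    nodes = [trunk.nodes]
    segments = [trunk.segments]
    depth = [trunk.depth_label]
    terminals: list[np.ndarray] = []
    offset = trunk.n_nodes
    for attach_at, sub in attached:
        nodes.append(sub.nodes)
        segments.append(sub.segments + offset)
        segments.append(np.array([[attach_at, offset + sub.root]], dtype=np.int64))
        depth.append(sub.depth_label)
        terminals.append(sub.terminals + offset)
        offset += sub.n_nodes
    term = np.concatenate(terminals) if terminals else trunk.terminals
    return PurkinjeTree(np.vstack(nodes), np.vstack(segments), root=trunk.root,
                        terminals=term, depth_label=np.concatenate(depth))


def build_conduction_system(mesh: Mesh, transmural, apicobasal,
                            variant: str = "ap",
                            tree_params: FractalTreeParams | None = None,
                            az_mask: np.ndarray | None = None,
                            basal_exclusion: float = 0.8,
                            seed: int = 0) -> PurkinjeTree:
    """His bundle + fractal Purkinje trees realizing an architecture variant.

    Junction placement excludes the basal band (apicobasal coordinate
    above ``basal_exclusion``) and the RV septal and posterior regions.
    The ``be`` variant stays endocardial; all others start from the
    projected (intramyocardial) tree.
    """
    lm = _auto_landmarks(mesh)
    ab = apicobasal.values
    if variant in ("ap", "ap-e", "mi"):
        # apical-shift variants move the LV bundle-branch endpoints toward
        # the apex before the Purkinje trees are grown from them
        lv_ids = mesh.surface_tags["lv_endo"]
        apical = lv_ids[ab[lv_ids] <= 0.3]
        if len(apical):
            from scipy.spatial import cKDTree
            kd = cKDTree(mesh.nodes[apical])
            for key in ("lv_anterior", "lv_posterior"):
                _, j = kd.query(lm[key])
                lm[key] = mesh.nodes[apical[j]]
    his = conduction.build_his_bundle(mesh, lm, tol_cm=2.0)
    basal = np.flatnonzero(ab >= basal_exclusion)
    rv_post = mesh.surface_tags["rv_endo"][
        mesh.nodes[mesh.surface_tags["rv_endo"], 1]
        < np.quantile(mesh.nodes[mesh.surface_tags["rv_endo"], 1], 0.25)]
    excl_lv = basal
    excl_rv = np.unique(np.concatenate([basal, mesh.surface_tags["rv_septum"],
                                        rv_post]))
    p = tree_params or FractalTreeParams()
    subs = []
    for i, (name, surf_tag, excl) in enumerate((
            ("lv_anterior", "lv_endo", excl_lv),
            ("lv_posterior", "lv_endo", excl_lv),
            ("rv", "rv_endo", excl_rv))):
        sub = conduction.grow_fractal_tree(
            mesh, mesh.surface_tags[surf_tag], np.array([lm[name]]),
            params=p, exclusions=excl, rng_seed=seed + i)
        subs.append((int(his.terminals[i]), sub))
    tree = merge_trees(his, subs)
    if variant == "be":
        return conduction.apply_variant(tree, "be", mesh)
    tree = conduction.project_tree_depth(tree, mesh, transmural, 75.0,
                                         rng_seed=seed + 17)
    if variant == "bi":
        return tree
    if variant in ("rvs", "ap", "ap-e", "mi"):
        tree = conduction.apply_variant(tree, "rvs", mesh, rng_seed=seed + 23)
    if variant == "ap-e":
        return conduction.apply_variant(tree, "ap-e", mesh)
    if variant == "mi":
        tree = conduction.apply_variant(tree, "mi", mesh,
                                        transmural_coord=transmural,
                                        az_mask=az_mask, rng_seed=seed + 31)
    return tree


def _scenario_zones(cfg: ExperimentConfig, mesh: Mesh):
    """Zone labels (0=HZ,1=BZ,2=SZ) and the affected-zone mask."""
    if cfg.scenario == "healthy":
        return np.zeros(mesh.n_nodes, dtype=np.int64), np.array([], dtype=np.int64)
    span = mesh.nodes[:, 2]
    mid_z = 0.3 * span.max() + 0.7 * span.min()
    if cfg.scenario == "mi-lad-like":  # anterior LV/septal apex-ward core
        center = np.array([0.2, mesh.nodes[:, 1].max() * 0.7, mid_z])
    else:  # mi-lcx-like: lateral LV free wall
        center = np.array([mesh.nodes[:, 0].min() * 0.8, 0.0, mid_z])
    core_r, border_w = 0.6, 0.5
    lge = synthetic.make_lge_intensity(mesh, center, core_r, border_w,
                                       levels=(30.0, 55.0, 100.0),
                                       noise_sd=2.0, seed=cfg.seed)
    d = np.linalg.norm(mesh.nodes - center, axis=1)
    az = np.flatnonzero(d <= core_r + border_w * 1.5)
    remote = np.flatnonzero(d > core_r + border_w * 3.0)
    if len(az) == 0 or len(remote) == 0:
        raise ValueError("infarct surrogate does not fit inside the mesh")
    _, zones = anatomy.segment_mi_fwhm(lge, az, remote)
    return zones, az


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full pipeline for one configuration.

    Returns the report dictionary (also written to ``report.json`` in
    the output directory together with the mesh, tree, signal and map
    artifacts). Analysis always uses the last simulated cycle.
    """
    cfg = config
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "config_hash": cfg.hash(),
                    "stages": {}}
    t_start = time.time()

    def stage(name):
        report["stages"][name] = round(time.time() - t_start, 2)

    # 1. anatomy
    mesh = make_biv_mesh(target_edge_um=cfg.target_edge_um)
    labels, tm, ab = anatomy.label_regions(mesh)
    zones, az_mask = _scenario_zones(cfg, mesh)
    labels.zone = zones
    stage("anatomy")

    # 2. fibers
    std = fibers.RBMAngles()
    rv_mask = np.zeros(mesh.n_nodes, bool)
    rv_mask[mesh.surface_tags["rv_endo"]] = True
    # element-wise RV membership: elements nearer the RV cavity than the LV
    elem_rv = rv_mask[mesh.tets].mean(axis=1) > 0.5
    if cfg.fiber_source == "dw-calibrated":
        ref = fibers.rbm_fiber_field(mesh, tm, ab, elem_rv, std)
        angles, _ = fibers.calibrate_rbm_angles(mesh, tm, ab, elem_rv, ref)
    else:
        angles = std
    fiber_field = fibers.rbm_fiber_field(mesh, tm, ab, elem_rv, angles)
    report["rbm_angles"] = asdict(angles)
    stage("fibers")

    # 3. conduction system
    tree = build_conduction_system(mesh, tm, ab, variant=cfg.cs_variant,
                                   az_mask=az_mask, seed=cfg.seed)
    coupling = conduction.couple_pmjs(tree, mesh, cfg.pmj_radius_mm)
    stage("conduction_system")

    # 4. cellular calibration
    model = TwoCurrentModel()
    spec = APDSHSpec(mode=cfg.apdsh_mode)
    regions = spec.regions()
    targets = np.array([spec.region_targets[r] for r in regions])
    mults, achieved, conv = tune_apd_control_batch(model, targets)
    tuned = dict(zip(regions, mults))
    apd_field = build_apdsh_map(labels, spec, tuned)
    exc_field = np.ones(mesh.n_nodes)
    apd_field = np.where(zones == 1, cfg.bz_apd_control * apd_field, apd_field)
    exc_field = np.where(zones == 1, cfg.bz_excitability, exc_field)
    report["apdsh"] = {"mode": cfg.apdsh_mode,
                       "targets_ms": targets.tolist(),
                       "achieved_ms": np.round(achieved, 2).tolist(),
                       "converged": [bool(c) for c in conv]}
    state, base_apd, _ = prepace_cell(model, cfg.cycle_length_ms, min_beats=5)
    stage("calibration")

    # 5. propagation
    dspec = DiffusionSpec()
    dspec.ldc[1] = cfg.bz_ldc
    op = assemble_diffusion(mesh, fiber_field, dspec, zone_labels=zones)
    duration = cfg.cycle_length_ms * cfg.n_cycles
    av_global = mesh.n_nodes + tree.root
    stimuli = [Stimulus(np.array([av_global]), k * cfg.cycle_length_ms + 1.0)
               for k in range(cfg.n_cycles)]
    hist = run_monodomain(mesh, op, model, duration, stimuli,
                          cs_tree=tree, cs_coupling=coupling,
                          diffusion_spec=dspec, initial_state=state,
                          apd_control_field=apd_field,
                          excitability_field=exc_field)
    stage("propagation")

    # 6. analysis of the last cycle
    last0 = (cfg.n_cycles - 1) * cfg.cycle_length_ms
    sel = hist.times >= last0 - 1e-9
    from bivtwin.propagation import VmHistory
    last = VmHistory(hist.times[sel] - last0, hist.vm[:, sel],
                     n_mesh_nodes=hist.n_mesh_nodes)
    at_all = signals.activation_map(last)
    at_myo = at_all.values[:mesh.n_nodes]
    at_cs = at_all.values[mesh.n_nodes:]
    apd_map = signals.apd90_map(VmHistory(last.times, last.mesh_block(),
                                          n_mesh_nodes=mesh.n_nodes))
    # neighbourhood radius covers the mesh edge length (600 um at the
    # study resolution; scaled up on coarser desk-scale meshes)
    cv_radius = max(0.06, 1.2 * mesh.edge_length_stats()["mean"] * 1e-4)
    cv_vec, cv_mag = signals.cv_map(at_myo, mesh.nodes, radius=cv_radius)
    pmjm = conduction.pmj_metrics(coupling, tree, at_cs, at_myo)
    layout = signals.ElectrodeLayout.default(center=mesh.nodes.mean(axis=0))
    pecg = signals.compute_pecg(last, mesh, op.tensors, layout)
    leads = signals.derive_12_leads(pecg)
    leads_f = signals.filter_normalize(leads, hp_hz=None)

    sz_nodes = np.flatnonzero(zones == 2)
    act = np.isfinite(at_myo)
    report["analysis"] = {
        "analysis_cycle": cfg.n_cycles,
        "activated_fraction": float(act.mean()),
        "at_ms": {"min": float(np.nanmin(at_myo[act])) if act.any() else None,
                  "max": float(np.nanmax(at_myo[act])) if act.any() else None},
        "apd90_ms": {"median": float(np.median(apd_map.values[np.isfinite(apd_map.values)]))},
        "cv_cm_s": {"median": float(np.nanmedian(cv_mag) * 1000.0)},
        "pmj_metrics": asdict(pmjm),
        "sz_never_activated": bool(np.all(~act[sz_nodes])) if len(sz_nodes) else None,
        "base_apd90_ms": float(np.atleast_1d(base_apd)[0]),
    }
    stage("analysis")

    # 7. artifacts
    vtuio.write_vtu(out / "mesh.vtu", mesh, {
        "transmural": tm.values, "apicobasal": ab.values,
        "zone": zones.astype(float),
        "transmural_label": labels.transmural.astype(float),
        "apicobasal_label": labels.apicobasal.astype(float),
        "at_ms": np.nan_to_num(at_myo, posinf=-1.0),
        "apd90_ms": np.nan_to_num(apd_map.values, posinf=-1.0),
        "cv_cm_s": np.nan_to_num(cv_mag * 1000.0, nan=-1.0),
    })
    vtuio.write_tree_json(out / "tree.json", tree)
    vtuio.write_signal_txt(out / "pecg_12lead.txt", leads_f)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def slab_pmj_testbed(edge_um: float = 1000.0, extent=(1.2, 1.2, 0.25),
                     n_terminals: int = 9, seed: int = 0):
    """Compact slab + toy conduction tree for junction-radius studies.

    A star-shaped tree above the slab surface feeds ``n_terminals``
    junctions spread over the endocardial face; the tree root is the
    stimulation site.
    """
    mesh = make_slab_mesh(extent, edge_um)
    rng = np.random.default_rng(seed)
    ext = np.asarray(extent)
    k = int(np.ceil(np.sqrt(n_terminals)))
    xs = np.linspace(0.2, ext[0] - 0.2, k)
    ys = np.linspace(0.2, ext[1] - 0.2, k)
    pts = np.array([[x, y, 0.02] for x in xs for y in ys][:n_terminals])
    pts[:, :2] += rng.normal(0, 0.01, size=(len(pts), 2))
    # hover each terminal right above a surface node so the junction
    # radius, not lateral snapping error, controls connectivity
    surf = mesh.nodes[mesh.surface_tags["endo"]]
    from scipy.spatial import cKDTree
    _, near = cKDTree(surf[:, :2]).query(pts[:, :2])
    pts[:, :2] = surf[near, :2]
    root = np.array([[ext[0] / 2.0, ext[1] / 2.0, 0.15]])
    nodes = [root[0]]
    segments = []
    terminals = []
    for i, p in enumerate(pts):
        # penultimate node just above the terminal: short last segment, as
        # in a fine fractal tree, so the anterograde lead window is usable
        pen = p + np.array([0.0, 0.0, 0.08])
        nodes += [pen, p]
        segments += [(0, len(nodes) - 2), (len(nodes) - 2, len(nodes) - 1)]
        terminals.append(len(nodes) - 1)
    tree = PurkinjeTree(np.array(nodes), np.array(segments), root=0,
                        terminals=np.array(terminals, dtype=np.int64))
    return mesh, tree


def pmj_radius_sweep(radii, mesh: Mesh | None = None,
                     tree: PurkinjeTree | None = None,
                     model: TwoCurrentModel | None = None,
                     duration_ms: float = 60.0,
                     junction_conductance: float = 8e-3) -> pd.DataFrame:
    """Couple + simulate + junction metrics for each radius.

    Returns a table with columns ``radius_mm``, ``ncPMJ``, ``cpPMJ``,
    ``aPMJ``. Defaults to the slab testbed.
    """
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    if mesh is None or tree is None:
        mesh, tree = slab_pmj_testbed()
    m = model or TwoCurrentModel()
    state, _, _ = prepace_cell(m, min_beats=4)
    fiber = FiberFieldUniform(mesh)
    spec = DiffusionSpec()
    op = assemble_diffusion(mesh, fiber, spec)
    rows = []
    for r in radii:
        coupling = conduction.couple_pmjs(tree, mesh, r)
        stim = Stimulus(np.array([mesh.n_nodes + tree.root]), 1.0)
        hist = run_monodomain(mesh, op, m, duration_ms, [stim],
                              cs_tree=tree, cs_coupling=coupling,
                              diffusion_spec=spec, initial_state=state,
                              junction_conductance=junction_conductance)
        at = signals.activation_map(hist).values
        met = conduction.pmj_metrics(coupling, tree, at[mesh.n_nodes:],
                                     at[:mesh.n_nodes])
        rows.append({"radius_mm": r, "ncPMJ": met.ncPMJ, "cpPMJ": met.cpPMJ,
                     "aPMJ": met.aPMJ})
    return pd.DataFrame(rows)


def FiberFieldUniform(mesh: Mesh):
    from bivtwin.fibers import FiberField

    return FiberField(np.tile([1.0, 0.0, 0.0], (mesh.n_tets, 1)))
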