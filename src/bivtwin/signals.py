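"""Pseudo-ECG computation and ECG / optical-mapping analytics.

The pseudo-ECG evaluates the infinite-medium dipole-source integral

    phi(e) = integral( -D grad(Vm) . grad(1/||r - e||) ) dr

per electrode by element-wise P1 gradients and one-point quadrature;
because the integrand is linear in the nodal voltages, the whole
computation collapses to one precomputed lead-field matrix applied to
the voltage history. Standard 12-lead algebra (Einthoven, Goldberger,
Wilson) derives the clinical leads from the nine electrode potentials.

Map analytics follow the conventions used throughout: activation at the
upward 0 mV crossing (simulations) or the maximum positive derivative
(optical maps), APD90 from the maximum-derivative upstroke to 90 %
recovery toward the diastolic level, and conduction velocity as the
mean pairwise displacement-over-delay vector within a spatial
neighborhood (600 um on meshes, 3 pixels on optical grids).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from bivtwin.anatomy import ScalarField, element_gradients
from bivtwin.mesh import Mesh
from bivtwin.propagation import VmHistory
from bivtwin.synthetic import MultiLeadSignal, OMRecording

__all__ = [
    "ElectrodeLayout",
    "MapBundle",
    "compute_pecg",
    "lead_field_matrix",
    "derive_12_leads",
    "filter_normalize",
    "median_beat",
    "segment_qrs_t",
    "waveform_similarity",
    "activation_map",
    "apd90_map",
    "cv_map",
    "process_om",
]

ELECTRODE_NAMES = ("RA", "LA", "RL", "LL", "V1", "V2", "V3", "V4", "V5", "V6")
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class ElectrodeLayout:
    """Named electrode positions (cm) in the heart frame.

    The default places the limb electrodes and the six precordials on a
    25 cm sphere around a given center in an anatomical-ish arrangement;
    the right-leg electrode is carried as reference only. ``transform``
    applies a rigid rotation + translation of the heart-electrode
    relative position (the HERP adjustment).
    """

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(ELECTRODE_NAMES) - set(self.positions)
        if missing:
            raise ValueError(f"missing electrodes: {sorted(missing)}")
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}

    @classmethod
    def default(cls, center=(0.0, 0.0, -1.5), radius_cm: float = 25.0) -> "ElectrodeLayout":
        c = np.asarray(center, float)

        def sph(theta_deg, phi_deg):
            th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
            return c + radius_cm * np.array([np.sin(th) * np.cos(ph),
                                             np.sin(th) * np.sin(ph),
                                             np.cos(th)])

        pos = {
            "RA": sph(60.0, 150.0),
            "LA": sph(60.0, 30.0),
            "RL": sph(150.0, 150.0),
            "LL": sph(150.0, 30.0),
        }
        for i, phi in enumerate((-60.0, -40.0, -20.0, 0.0, 20.0, 40.0)):
            pos[f"V{i + 1}"] = sph(95.0, phi)
        return cls(pos)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0)) -> "ElectrodeLayout":
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        t = np.asarray(translation, float)
        return ElectrodeLayout({k: R @ v + t for k, v in self.positions.items()})


@dataclass
class MapBundle:
    """Derived activation / repolarization / velocity maps."""

    at: np.ndarray
    apd90: np.ndarray
    cv_vectors: np.ndarray | None = None
    cv_magnitude: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def lead_field_matrix(mesh: Mesh, tensors: np.ndarray,
                      layout: ElectrodeLayout,
                      electrodes=None) -> tuple[np.ndarray, list[str]]:
    """Precompute the (n_electrodes, n_nodes) map from nodal Vm to the
    dipole-integral potentials. Electrodes must lie outside the mesh."""
    names = [n for n in (electrodes or ELECTRODE_NAMES) if n != "RL"]
    g = element_gradients(mesh)  # (M,4,3)
    vol = mesh.tet_volumes
    centers = mesh.nodes[mesh.tets].mean(axis=1)
    bbox_lo, bbox_hi = mesh.nodes.min(0), mesh.nodes.max(0)

    # Dg maps the 4 nodal values of each element to D grad(Vm)
    Dg = np.einsum("mab,mib->mia", tensors, g)  # (M,4,3)
    L = np.zeros((len(names), mesh.n_nodes))
    for k, name in enumerate(names):
        e = layout.positions[name]
        if np.all(e >= bbox_lo) and np.all(e <= bbox_hi):
            raise ValueError(f"electrode {name} lies inside the mesh bounding box")
        r = centers - e
        dist3 = np.linalg.norm(r, axis=1) ** 3
        # -D grad(Vm) . grad(1/|r-e|) = (D grad Vm) . (r-e)/|r-e|^3
        w = np.einsum("mia,ma->mi", Dg, r / dist3[:, None]) * vol[:, None]
        np.add.at(L[k], mesh.tets.ravel(), w.ravel())
    return L, names


def compute_pecg(vm: VmHistory, mesh: Mesh, tensors: np.ndarray,
                 layout: ElectrodeLayout) -> MultiLeadSignal:
    """Pseudo-ECG electrode potentials (nine electrodes, RL excluded)."""
    L, names = lead_field_matrix(mesh, tensors, layout)
    phi = L @ vm.mesh_block()
    rate = 1000.0 / vm.dt if vm.dt > 0 else 1000.0
    return MultiLeadSignal(phi, rate, names)


def derive_12_leads(potentials: MultiLeadSignal) -> MultiLeadSignal:
    """Standard 12-lead algebra from electrode potentials.

    Einthoven limb leads, Goldberger augmented leads, and Wilson central
    terminal referenced precordials.
    """
    req = ["RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6"]
    missing = [r for r in req if r not in potentials.channel_names]
    if missing:
        raise ValueError(f"missing electrodes: {missing}")
    ra, la, ll = (potentials.channel(n) for n in ("RA", "LA", "LL"))
    wct = (ra + la + ll) / 3.0
    leads = [
        la - ra,  # I
        ll - ra,  # II
        ll - la,  # III
        ra - (la + ll) / 2.0,  # aVR
        la - (ra + ll) / 2.0,  # aVL
        ll - (ra + la) / 2.0,  # aVF
    ] + [potentials.channel(f"V{i}") - wct for i in range(1, 7)]
    return MultiLeadSignal(np.array(leads), potentials.sampling_rate,
                           list(LEAD_NAMES), fiducials=potentials.fiducials)


def filter_normalize(sig: MultiLeadSignal, hp_hz: float | None = 0.5,
                     lp_hz: float = 40.0, normalize: bool = True,
                     order: int = 4) -> MultiLeadSignal:
    """Zero-phase Butterworth filtering, baseline zeroing, normalization.

    High- and low-pass cutoffs default to 0.5 and 40 Hz; the baseline
    (per-lead median) is subtracted and each lead is scaled to unit
    maximum absolute value.
    """
    nyq = sig.sampling_rate / 2.0
    if lp_hz >= nyq or (hp_hz is not None and hp_hz >= nyq):
        raise ValueError("cutoff must be below the Nyquist frequency")
    x = sig.samples
    sos = sps.butter(order, lp_hz, btype="low", fs=sig.sampling_rate, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    if hp_hz is not None and hp_hz > 0:
        sos = sps.butter(order, hp_hz, btype="high", fs=sig.sampling_rate, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
    x = x - np.median(x, axis=1, keepdims=True)
    if normalize:
        peak = np.abs(x).max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        x = x / peak
    return MultiLeadSignal(x, sig.sampling_rate, list(sig.channel_names),
                           fiducials=sig.fiducials)


def median_beat(sig: MultiLeadSignal, fiducials: np.ndarray | None = None,
                window_ms: tuple[float, float] = (240.0, 538.0),
                corr_threshold: float = 0.9) -> tuple[MultiLeadSignal, np.ndarray]:
    """Median beat per lead with correlation-based outlier rejection.

    Beats are cropped around each fiducial (default 240 ms before and
    538 ms after); the representative beat maximizes the summed
    correlation with all beats of the lead; beats correlating with it at
    or below the threshold are excluded and the sample-wise median of
    the rest is returned, along with the per-lead inclusion mask.
    """
    fid = sig.fiducials if fiducials is None else np.asarray(fiducials, float)
    if fid is None or len(fid) == 0:
        raise ValueError("at least one fiducial is required")
    fs = sig.sampling_rate
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    width = pre + post
    n_ch = sig.samples.shape[0]

    beats = []
    for f_ms in fid:
        c = int(round(f_ms * fs / 1000.0))
        lo, hi = c - pre, c + post
        seg = np.zeros((n_ch, width))
        s_lo, s_hi = max(lo, 0), min(hi, sig.n_samples)
        seg[:, s_lo - lo:s_lo - lo + (s_hi - s_lo)] = sig.samples[:, s_lo:s_hi]
        beats.append(seg)
    B = np.array(beats)  # (n_beats, n_ch, width)
    n_beats = len(B)

    included = np.zeros((n_ch, n_beats), dtype=bool)
    med = np.empty((n_ch, width))
    for c in range(n_ch):
        X = B[:, c, :]
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        norms[norms == 0] = 1.0
        C = (Xc @ Xc.T) / np.outer(norms, norms)
        rep = int(np.argmax(C.sum(axis=1)))
        ok = C[rep] > corr_threshold
        if not ok.any():
            warnings.warn(f"no beat passes the correlation threshold in lead {c}; "
                          "returning the representative beat")
            med[c] = X[rep]
            included[c, rep] = True
        else:
            med[c] = np.median(X[ok], axis=0)
            included[c] = ok
    return MultiLeadSignal(med, fs, list(sig.channel_names)), included


def _mean_peak_time(samples: np.ndarray, times: np.ndarray,
                    lo_ms: float, hi_ms: float) -> float:
    """Average per-lead |amplitude|-peak time within [lo, hi) ms; flat
    leads are excluded."""
    sel = (times >= lo_ms) & (times < hi_ms)
    peaks = []
    for lead in samples:
        seg = lead[sel]
        if np.ptp(seg) == 0:
            continue
        peaks.append(times[sel][int(np.argmax(np.abs(seg)))])
    if not peaks:
        raise ValueError("all leads are flat in the search window")
    return float(np.mean(peaks))


def segment_qrs_t(sim: MultiLeadSignal, exp: MultiLeadSignal,
                  qrs_half_ms: float = 50.0, t_half_ms: float = 100.0,
                  qrs_search_fraction: float = 0.4):
    """Crop aligned QRS and T-wave windows from two beats.

    The QRS peak is searched in the first ``qrs_search_fraction`` of the
    beat and the T peak in the remainder; each window spans +-50 ms
    (QRS) / +-100 ms (T) around the mean (across leads) peak time of its
    own signal. Returns ``{"qrs": (sim_win, exp_win), "t": ...}`` of
    equal-width sample arrays.
    """
    out = {}
    windows = {"qrs": qrs_half_ms, "t": t_half_ms}
    for wave, half in windows.items():
        pair = []
        for s in (sim, exp):
            t = s.times_ms
            split = t[-1] * qrs_search_fraction
            lo, hi = (0.0, split) if wave == "qrs" else (split, t[-1] + 1e-9)
            center = _mean_peak_time(s.samples, t, lo, hi)
            sel = (t >= center - half) & (t <= center + half)
            pair.append(s.samples[:, sel])
        w = min(p.shape[1] for p in pair)
        out[wave] = (pair[0][:, :w], pair[1][:, :w])
    return out


def waveform_similarity(a: np.ndarray, b: np.ndarray):
    """Per-lead Pearson correlation and its mean across usable leads.

    Zero-variance windows are excluded (r undefined there) and reported
    as NaN in the per-lead vector.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape != b.shape:
        raise ValueError("windows must have equal shapes")
    r = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        x, y = a[i] - a[i].mean(), b[i] - b[i].mean()
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            continue
        r[i] = float(x @ y / (nx * ny))
    ok = np.isfinite(r)
    return r, (float(r[ok].mean()) if ok.any() else float("nan"))


def activation_map(vm: VmHistory, threshold_mv: float = 0.0,
                   method: str = "crossing") -> ScalarField:
    """Activation time per node.

    ``crossing``: first upward crossing of the threshold (0 mV), linearly
    interpolated between output samples; ``derivative``: time of the
    maximum positive temporal derivative (the optical-mapping variant).
    Sites that never activate get NaN.
    """
    V = vm.vm
    t = vm.times
    at = np.full(V.shape[0], np.nan)
    if method == "derivative":
        dv = np.diff(V, axis=1)
        rising = dv.max(axis=1) > 0
        idx = np.argmax(dv, axis=1)
        at[rising] = t[idx[rising]] + 0.5 * vm.dt
        return ScalarField(np.nan_to_num(at, nan=np.inf), units="ms", allow_undefined=True)
    above = V >= threshold_mv
    new_cross = (~above[:, :-1]) & above[:, 1:]
    has = new_cross.any(axis=1)
    first = np.argmax(new_cross, axis=1)
    rows = np.flatnonzero(has)
    j = first[rows]
    v0, v1 = V[rows, j], V[rows, j + 1]
    frac = np.where(v1 != v0, (threshold_mv - v0) / (v1 - v0), 0.0)
    at[rows] = t[j] + frac * vm.dt
    return ScalarField(np.nan_to_num(at, nan=np.inf), units="ms", allow_undefined=True)


def apd90_map(vm: VmHistory, repol_fraction: float = 0.9) -> ScalarField:
    """APD90 per node: maximum-derivative upstroke to 90 % recovery from
    the peak toward the diastolic (initial) level, linearly interpolated.
    Nodes without a complete repolarization get +inf."""
    V = vm.vm
    t = vm.times
    n = V.shape[0]
    out = np.full(n, np.inf)
    dv = np.diff(V, axis=1)
    i_up = np.argmax(dv, axis=1)
    for i in range(n):
        iu = i_up[i]
        if dv[i, iu] <= 0:
            continue
        ip = iu + int(np.argmax(V[i, iu:]))
        diastolic = V[i, 0]
        level = V[i, ip] - repol_fraction * (V[i, ip] - diastolic)
        seg = V[i, ip:]
        below = np.flatnonzero(seg <= level)
        if len(below) == 0:
            continue
        j = ip + below[0]
        if j == 0 or V[i, j] == V[i, j - 1]:
            t_rep = t[j]
        else:
            frac = (V[i, j - 1] - level) / (V[i, j - 1] - V[i, j])
            t_rep = t[j - 1] + frac * (t[j] - t[j - 1])
        out[i] = t_rep - (t[iu] + 0.5 * vm.dt)
    return ScalarField(out, units="ms", allow_undefined=True)


def cv_map(at: np.ndarray, positions: np.ndarray, radius: float,
           min_dt_ms: float = 0.01):
    """Conduction-velocity vectors from activation-time differences.

    For each site, the velocity to every neighbor within ``radius`` (same
    length unit as ``positions``) is displacement / delay; pairs with
    |delay| below ``min_dt_ms`` are excluded (unbounded speed), and the
    site's vector is the mean of the rest. Sites with no usable neighbor
    get NaN vectors.
    """
    at = np.asarray(at, float)
    pos = np.asarray(positions, float)
    finite = np.isfinite(at)
    vec = np.full((len(at), pos.shape[1]), np.nan)
    mag = np.full(len(at), np.nan)
    kd = cKDTree(pos[finite])
    fin_idx = np.flatnonzero(finite)
    pairs = kd.query_ball_point(pos[finite], radius)
    for local_i, neigh in enumerate(pairs):
        i = fin_idx[local_i]
        vs = []
        for local_j in neigh:
            j = fin_idx[local_j]
            if j == i:
                continue
            dt = at[j] - at[i]
            if abs(dt) < min_dt_ms:
                continue
            vs.append((pos[j] - pos[i]) / dt)
        if vs:
            vec[i] = np.mean(vs, axis=0)
            mag[i] = np.linalg.norm(vec[i])
    return vec, mag


def process_om(recording: OMRecording, hp_hz: float = 0.4,
               cycle_length_ms: float = 1000.0,
               sigma_space_px: float = 1.0, sigma_time_frames: float = 1.0,
               snr_floor: float = 4.0, cv_radius_px: float = 3.0) -> MapBundle:
    """Optical-mapping pipeline: drift removal, smoothing, median maps.

    Per-pixel high-pass filtering (0.4 Hz) removes baseline drift;
    spatio-temporal Gaussian smoothing (sigma doubled where the local
    SNR estimate falls below ``snr_floor``) suppresses noise; per-beat
    activation (maximum positive derivative) and APD90 are extracted on
    each full pacing cycle and their per-pixel medians across beats form
    the maps. Velocity uses the 3-pixel neighborhood rule.
    """
    if not recording.roi_mask.any():
        raise ValueError("empty region of interest")
    fs = recording.sampling_rate
    frames = recording.frames.astype(float)
    n_frames = frames.shape[0]
    frames_per_beat = int(round(cycle_length_ms * fs / 1000.0))
    n_beats = n_frames // frames_per_beat
    if n_beats < 1:
        raise ValueError("recording shorter than one pacing cycle")

    if hp_hz and hp_hz > 0:
        sos = sps.butter(2, hp_hz, btype="high", fs=fs, output="sos")
        flat = frames.reshape(n_frames, -1)
        flat = sps.sosfiltfilt(sos, flat, axis=0)
        frames = flat.reshape(frames.shape)

    # adaptive smoothing: double sigma where the SNR estimate is poor
    noise = np.median(np.abs(np.diff(frames, axis=0)), axis=0) / 0.6745 + 1e-12
    snr = frames.std(axis=0) / noise
    smooth = gaussian_filter(frames, (sigma_time_frames, sigma_space_px, sigma_space_px))
    heavy = gaussian_filter(frames, (2 * sigma_time_frames, 2 * sigma_space_px,
                                     2 * sigma_space_px))
    frames = np.where((snr < snr_floor)[None], heavy, smooth)

    H, W = frames.shape[1:]
    at_beats = np.full((n_beats, H, W), np.nan)
    apd_beats = np.full((n_beats, H, W), np.nan)
    dt_ms = 1000.0 / fs
    for b in range(n_beats):
        seg = frames[b * frames_per_beat:(b + 1) * frames_per_beat]
        dv = np.diff(seg, axis=0)
        i_up = np.argmax(dv, axis=0)
        rising = np.take_along_axis(dv, i_up[None], axis=0)[0] > 0
        at_rel = (i_up + 0.5) * dt_ms
        at_beats[b][rising] = at_rel[rising]
        # APD90 per pixel
        i_pk = np.argmax(seg, axis=0)
        peak = seg.max(axis=0)
        diast = np.quantile(seg, 0.05, axis=0)
        level = peak - 0.9 * (peak - diast)
        for (y, x) in zip(*np.nonzero(recording.roi_mask & rising)):
            tail = seg[i_pk[y, x]:, y, x]
            below = np.flatnonzero(tail <= level[y, x])
            if len(below) == 0:
                continue
            j = i_pk[y, x] + below[0]
            apd_beats[b, y, x] = j * dt_ms - at_rel[y, x]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        at_med = np.nanmedian(at_beats, axis=0)
        apd_med = np.nanmedian(apd_beats, axis=0)
    at_med[~recording.roi_mask] = np.nan
    apd_med[~recording.roi_mask] = np.nan

    ys, xs = np.nonzero(recording.roi_mask)
    pix_pos = np.column_stack([xs, ys]).astype(float)
    vec_flat, mag_flat = cv_map(at_med[ys, xs], pix_pos, cv_radius_px)
    # px/ms -> cm/s
    scale = recording.pixel_size * 1000.0
    cv_mag = np.full((H, W), np.nan)
    cv_mag[ys, xs] = mag_flat * scale
    return MapBundle(at=at_med, apd90=apd_med, cv_vectors=vec_flat * scale,
                     cv_magnitude=cv_mag,
                     meta={"n_beats": n_beats, "sampling_rate": fs})
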