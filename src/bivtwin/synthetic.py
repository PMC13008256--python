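"""Synthetic stand-ins for the study's imaging and signal inputs.

Every generator is deterministic under a fixed seed: randomness flows
from a single integer through ``numpy.random.default_rng`` spawned
per call, never through global state. The generators are built so the
corresponding analysis stage inverts them exactly in the noiseless limit
(tensor fit recovers the planted diffusion tensors, the median beat
recovers the template, the optical-map extraction recovers the planted
activation/duration maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bivtwin.anatomy import ScalarField
from bivtwin.mesh import Mesh

__all__ = [
    "DWSignalSet",
    "OMRecording",
    "MultiLeadSignal",
    "make_lge_intensity",
    "make_dw_signals",
    "make_ecg_beats",
    "make_om_movie",
    "default_ecg_template",
    "uniform_sphere_gradients",
    "stylized_ap_trace",
]


@dataclass
class DWSignalSet:
    """Diffusion-weighted signal set: S[n, g] for unit gradients g.

    ``b_value`` in s/mm^2, signals attenuated from the gradient-free
    baseline ``s0`` by the Stejskal-Tanner factor exp(-b g^T D g).
    """

    gradients: np.ndarray
    b_value: float
    s0: float
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        norms = np.linalg.norm(self.gradients, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("gradient directions must be unit vectors")
        if np.any(self.signals <= 0) or np.any(self.signals > self.s0 * (1 + 1e-12)):
            raise ValueError("signals must lie in (0, s0]")


@dataclass
class OMRecording:
    """Optical-mapping movie: fluorescence frames (a.u.) on a pixel grid."""

    frames: np.ndarray  # (T, H, W)
    pixel_size: float  # cm / pixel
    sampling_rate: float  # Hz
    roi_mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.frames = np.asarray(self.frames, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.roi_mask.shape != self.frames.shape[1:]:
            raise ValueError("roi_mask must match the frame grid")


@dataclass
class MultiLeadSignal:
    """Time-sampled multi-channel signal (mV) with optional beat fiducials."""

    samples: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float  # Hz
    channel_names: list[str]
    fiducials: np.ndarray | None = None  # ms, strictly increasing

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names must match the number of channels")
        if self.fiducials is not None:
            self.fiducials = np.asarray(self.fiducials, dtype=float)
            if np.any(np.diff(self.fiducials) <= 0):
                raise ValueError("fiducials must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


def make_lge_intensity(mesh: Mesh, core_center, core_radius: float,
                       border_width: float, levels=(30.0, 55.0, 100.0),
                       noise_sd: float = 0.0, seed: int = 0) -> ScalarField:
    """Late-enhancement intensity surrogate: bright core, graded border.

    Intensity equals the core level inside ``core_radius``, ramps
    smoothly (cosine taper) to the remote level across ``border_width``,
    and is flat outside; optional additive Gaussian noise. Levels must be
    strictly increasing (remote < border < core); the border level is the
    ramp's mid value. A Gaussian additive noise model is assumed for the
    surrogate since no intensity noise model is prescribed for this kind
    of data.
    """
    remote, border, core = (float(v) for v in levels)
    if not (remote < border < core):
        raise ValueError("levels must be strictly increasing (remote, border, core)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if core_radius <= 0 or border_width <= 0:
        raise ValueError("core_radius and border_width must be positive")
    d = np.linalg.norm(mesh.nodes - np.asarray(core_center, float), axis=1)
    t = np.clip((d - core_radius) / border_width, 0.0, 1.0)
    ramp = 0.5 * (1.0 + np.cos(np.pi * t))  # 1 at the core edge, 0 outside
    values = remote + (core - remote) * ramp
    values[d <= core_radius] = core
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return ScalarField(values, units="a.u.")


def uniform_sphere_gradients(n: int, seed: int = 0) -> np.ndarray:
    """n approximately uniformly spread unit directions (Fibonacci sphere)."""
    if n < 6:
        raise ValueError("at least 6 gradient directions are required")
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    g = np.column_stack([np.sin(phi) * np.cos(theta),
                         np.sin(phi) * np.sin(theta),
                         np.cos(phi)])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def make_dw_signals(tensors: np.ndarray, gradients: np.ndarray,
                    b_value: float = 1000.0, s0: float = 1000.0,
                    noise_sd: float = 0.0, seed: int = 0) -> DWSignalSet:
    """Stejskal-Tanner forward model: S = s0 exp(-b g^T D g) + noise.

    ``tensors`` is (N, 3, 3) symmetric positive semi-definite in mm^2/s
    (b in s/mm^2 makes the exponent dimensionless). Noisy signals are
    clipped into (0, s0] so downstream log-domain fitting stays defined.
    """
    D = np.asarray(tensors, dtype=float)
    if D.ndim == 2:
        D = D[None]
    if not np.allclose(D, np.transpose(D, (0, 2, 1)), atol=1e-10):
        raise ValueError("tensors must be symmetric")
    if np.any(np.linalg.eigvalsh(D) < -1e-12):
        raise ValueError("tensors must be positive semi-definite")
    if b_value < 0:
        raise ValueError("b_value must be non-negative")
    g = np.asarray(gradients, dtype=float)
    g = g / np.linalg.norm(g, axis=1, keepdims=True)
    quad = np.einsum("ga,nab,gb->ng", g, D, g)
    signals = s0 * np.exp(-b_value * quad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
        signals = np.clip(signals, s0 * 1e-9, s0)
    return DWSignalSet(g, float(b_value), float(s0), signals)


def default_ecg_template(sampling_rate: float = 2000.0,
                         n_channels: int = 9,
                         duration_ms: float = 600.0) -> MultiLeadSignal:
    """Stylized one-beat electrode template (P-QRS-T-like morphology).

    Channels carry channel-specific linear mixes of a shared beat shape
    so lead-wise processing sees distinct but correlated morphologies.
    """
    t = np.arange(int(round(duration_ms * sampling_rate / 1000.0))) * 1000.0 / sampling_rate

    def gauss(mu, sd, amp):
        return amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)

    p = gauss(150.0, 18.0, 0.12)
    q = gauss(240.0, 6.0, -0.2)
    r = gauss(255.0, 8.0, 1.2)
    s = gauss(272.0, 7.0, -0.35)
    tw = gauss(450.0, 45.0, 0.4)
    base = p + q + r + s + tw
    alt = gauss(150.0, 18.0, 0.05) + gauss(258.0, 9.0, 0.8) + gauss(440.0, 50.0, 0.25)
    chans = []
    for c in range(n_channels):
        w = np.cos(2 * np.pi * c / n_channels)
        chans.append(w * base + (1 - abs(w)) * alt)
    names = ["RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6"][:n_channels]
    if n_channels > 9:
        names = names + [f"ch{i}" for i in range(9, n_channels)]
    return MultiLeadSignal(np.array(chans), sampling_rate, names)


def make_ecg_beats(template: MultiLeadSignal, n_beats: int, rr_ms: float = 769.0,
                   jitter_ms: float = 0.0, amp_noise: float = 0.0,
                   n_outliers: int = 0, seed: int = 0) -> MultiLeadSignal:
    """Multi-beat recording from a one-beat template.

    Beats are placed at jittered RR intervals with per-sample amplitude
    noise; ``n_outliers`` of them are replaced by morphology-corrupted
    copies constructed (time-reversal plus an orthogonalized residual) to
    correlate below 0.9 with the template on every channel. Fiducials
    mark each beat's onset (ms).
    """
    if n_outliers > n_beats:
        raise ValueError("n_outliers cannot exceed n_beats")
    tpl = template.samples
    n_ch, tpl_len = tpl.shape
    fs = template.sampling_rate
    rr_samp = rr_ms * fs / 1000.0
    if tpl_len > rr_samp:
        raise ValueError("template must be shorter than the RR interval")
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, jitter_ms, size=n_beats) if jitter_ms > 0 else np.zeros(n_beats)
    onsets_ms = np.arange(n_beats) * rr_ms + np.concatenate([[0.0], jitter[1:]])
    onsets_ms = np.maximum.accumulate(onsets_ms)  # keep strictly ordered
    onsets_ms += np.arange(n_beats) * 1e-9
    onset_samp = np.round(onsets_ms * fs / 1000.0).astype(int)

    total = onset_samp[-1] + tpl_len + int(rr_samp)
    out = np.zeros((n_ch, total))
    outlier_idx = rng.choice(n_beats, size=n_outliers, replace=False) if n_outliers else np.array([], int)

    for b in range(n_beats):
        beat = tpl.copy()
        if b in outlier_idx:
            beat = _corrupt_beat(tpl, rng)
        if amp_noise > 0:
            beat = beat + rng.normal(0.0, amp_noise, size=beat.shape)
        out[:, onset_samp[b]:onset_samp[b] + tpl_len] += beat
    return MultiLeadSignal(out, fs, list(template.channel_names), fiducials=onsets_ms)


def _corrupt_beat(tpl: np.ndarray, rng: np.random.Generator,
                  max_corr: float = 0.9) -> np.ndarray:
    """Morphology-corrupted copy guaranteed to correlate < max_corr per channel."""
    beat = tpl[:, ::-1].copy()
    for c in range(tpl.shape[0]):
        x = tpl[c] - tpl[c].mean()
        for _ in range(64):
            y = beat[c] - beat[c].mean()
            denom = np.linalg.norm(x) * np.linalg.norm(y)
            r = float(x @ y / denom) if denom > 0 else 0.0
            if abs(r) < max_corr - 0.05:
                break
            # remove the component along the template and add rough noise
            y = y - (x @ y) / (x @ x) * x
            y = y + rng.normal(0.0, 0.5 * np.abs(tpl[c]).max(), size=len(y))
            beat[c] = y
    return beat


def stylized_ap_trace(t_ms: np.ndarray, at_ms: float, apd_ms: float,
                      amplitude: float = 1.0, upstroke_ms: float = 1.5,
                      plateau_fraction: float = 0.6) -> np.ndarray:
    """Stylized optical action potential: sigmoid upstroke at ``at_ms``, a
    plateau, then exponential repolarization reaching 90 % recovery at
    ``at_ms + apd_ms`` (so the planted APD90 equals ``apd_ms``)."""
    from scipy.special import expit

    tau = np.asarray(t_ms, float) - at_ms
    up = expit(tau / (upstroke_ms / 4.0))
    t_pl = plateau_fraction * apd_ms
    lam = (apd_ms - t_pl) / np.log(10.0)
    rep = np.where(tau > t_pl, np.exp(-np.maximum(tau - t_pl, 0.0) / lam), 1.0)
    return amplitude * up * rep


def make_om_movie(at_map: np.ndarray, apd_map: np.ndarray, pixel_size: float,
                  sampling_rate: float = 500.0, drift_hz: float = 0.0,
                  noise_sd: float = 0.0, n_beats: int = 1,
                  cycle_length_ms: float = 1000.0, drift_amp: float = 0.3,
                  seed: int = 0, roi_mask: np.ndarray | None = None) -> OMRecording:
    """Synthesize a fluorescence movie from planted AT and APD90 maps.

    Each pixel traces the stylized AP repeated ``n_beats`` times at the
    pacing cycle length, plus a slow sinusoidal baseline drift at
    ``drift_hz`` and white Gaussian noise.
    """
    at = np.asarray(at_map, float)
    apd = np.asarray(apd_map, float)
    if at.shape != apd.shape:
        raise ValueError("AT and APD maps must share the same pixel grid")
    if sampling_rate < 100.0:
        raise ValueError("sampling_rate must be at least 100 Hz")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_frames = int(round(n_beats * cycle_length_ms * sampling_rate / 1000.0))
    t = np.arange(n_frames) * 1000.0 / sampling_rate  # ms
    frames = np.zeros((n_frames,) + at.shape)
    for b in range(n_beats):
        onset = b * cycle_length_ms
        tau = t[:, None, None] - (onset + at[None])
        from scipy.special import expit
        up = expit(tau / 0.375)
        t_pl = 0.6 * apd[None]
        lam = 0.4 * apd[None] / np.log(10.0)
        rep = np.where(tau > t_pl, np.exp(-np.maximum(tau - t_pl, 0.0) / lam), 1.0)
        # restrict each beat's contribution to its own cycle window
        window = (tau > -onset - 1e-9) if b == 0 else (t[:, None, None] >= onset)
        window = window & (t[:, None, None] < onset + cycle_length_ms)
        frames += np.where(window, up * rep, 0.0)
    if drift_hz > 0 and drift_amp != 0:
        frames = frames + drift_amp * np.sin(2 * np.pi * drift_hz * t / 1000.0)[:, None, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    mask = np.ones(at.shape, bool) if roi_mask is None else np.asarray(roi_mask, bool)
    return OMRecording(frames, float(pixel_size), float(sampling_rate), mask)
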