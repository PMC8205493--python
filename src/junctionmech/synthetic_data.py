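"""Synthetic data with the statistical structure of junction remodeling movies.

Every pipeline stage in this package is testable without any microscopy data:
the generators here emulate (i) persistent superdiffusive ("active") and
caged subdiffusive ("passive") vertex tracks at a 2 s frame interval,
(ii) shortening and non-shortening junction recordings driven by the
two-vertex viscoelastic model, (iii) intensity profiles with regularly
ordered ~1 μm cadherin-like clusters versus diffuse cluster-free signal, and
(iv) coupled length/cluster-size series in which cluster-size pulses lead
shortening pulses by a configurable lead time (~20 s).

Every generator is a pure function of its :class:`GeneratorConfig` (the seed
included): identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .junction_model import ModelParams, simulate_junction
from .tracks_io import (
    IntensityProfileSeries,
    JunctionRecording,
    VertexTrack,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults are the stated world of the recordings this package analyzes.

    Times in s, lengths in μm. ``cluster_length_scale`` (1.0 μm) is the
    cadherin cis-cluster scale read out by the spatial-autocorrelation zero
    crossing; ``cluster_spacing`` (5× that scale) was calibrated by
    simulation so the quasi-periodic cluster train's ensemble zero crossing
    reads out the stated scale as closely as the finite junction allows.
    ``lead_time`` (20 s) is the interval by which cluster-size pulses precede
    shortening-pulse onsets.
    """

    frame_interval: float = 2.0
    duration: float = 400.0
    pixel_size: float = 0.1
    junction_length: float = 12.0
    # --- intensity-profile generators ---
    cluster_length_scale: float = 1.0
    cluster_spacing: float = 5.0
    spacing_jitter: float = 0.1        # fraction of the spacing
    cluster_amplitude: float = 1.0     # a.u.
    amplitude_jitter: float = 0.3      # relative cluster-brightness dispersion
    width_jitter: float = 0.25         # relative cluster-width dispersion
    psf_sigma: float = 0.1             # μm, optical blur of cluster edges
    noise_sd: float = 0.1              # a.u., additive pixel noise
    # --- coupled length/cluster series ---
    lead_time: float = 20.0
    pulse_drop: float = 2.2            # μm lost per shortening pulse
    pulse_duration: float = 30.0       # s, raised-cosine drop duration
    length_noise_sd: float = 0.1       # μm, measurement noise on L(t)
    cluster_pulse_amplitude: float = 0.4   # μm, cluster-scale modulation depth
    cluster_pulse_sd: float = 8.0      # s, width of the cluster-scale pulse
    # --- track generators ---
    persistence_time: float = 30.0     # s, velocity-OU persistence (active)
    drift_speed: float = 0.01          # μm/s, directed component (active)
    speed_sd: float = 0.01             # μm/s, velocity-OU amplitude (active)
    cage_stiffness: float = 0.5        # s⁻¹, confinement rate (passive)
    cage_diffusivity: float = 0.011    # μm²/s; stationary sd = sqrt(D/k) ≈ 0.15 μm
    hop_rate: float = 0.005            # s⁻¹, Poisson cage-hop rate
    hop_size: float = 0.5              # μm
    seed: int = 0

    def __post_init__(self):
        for name in ("frame_interval", "duration", "pixel_size", "junction_length",
                     "cluster_length_scale", "cluster_spacing", "cluster_amplitude",
                     "persistence_time", "cage_stiffness", "cage_diffusivity",
                     "pulse_duration", "cluster_pulse_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_length_scale < 2 * self.pixel_size:
            raise ValueError("cluster_length_scale must be >= 2 pixels")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    def time_grid(self) -> np.ndarray:
        return self.frame_interval * np.arange(self.n_frames)


def _rng(config: GeneratorConfig, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# Vertex-track generators
# ---------------------------------------------------------------------------

def gen_persistent_track(
    config: GeneratorConfig, vertex_id: str = "active", stream: int = 1
) -> VertexTrack:
    """Persistent random walk with drift: the fluid-like active-vertex motion.

    Velocities follow a 2D Ornstein–Uhlenbeck process with persistence time
    longer than the frame interval, plus a constant drift along +x; the MSD
    exponent at intermediate lags lies in (1, 2), approaching 2 as the noise
    vanishes (pure drift).
    """
    rng = _rng(config, stream)
    t = config.time_grid()
    dt = config.frame_interval
    n = t.size
    v = np.zeros((n, 2))
    a = np.exp(-dt / config.persistence_time)
    sd_eq = config.speed_sd
    v[0] = rng.normal(0.0, sd_eq, 2) if sd_eq > 0 else 0.0
    kick = sd_eq * np.sqrt(1 - a * a)
    for i in range(n - 1):
        v[i + 1] = v[i] * a + (rng.normal(0.0, kick, 2) if kick > 0 else 0.0)
    vel = v + np.array([config.drift_speed, 0.0])
    pos = np.vstack([[0.0, 0.0], np.cumsum(vel[:-1] * dt, axis=0)])
    return VertexTrack(vertex_id, t, pos, frame_interval=dt)


def gen_caged_track(
    config: GeneratorConfig, vertex_id: str = "passive", stream: int = 2
) -> VertexTrack:
    """Confined motion with rare cage hops: the glass-like passive-vertex motion.

    The vertex relaxes (rate ``cage_stiffness`` k) toward a cage center and is
    driven with diffusivity D = ``cage_diffusivity``; its stationary spread is
    sqrt(D/k). The cage center jumps a distance ``hop_size`` in a random
    direction at Poisson rate ``hop_rate``. As k → 0 at fixed D the motion
    degenerates to a Brownian walk.
    """
    rng = _rng(config, stream)
    t = config.time_grid()
    dt = config.frame_interval
    n = t.size
    k = config.cage_stiffness
    D = config.cage_diffusivity
    decay = np.exp(-k * dt)
    kick_sd = np.sqrt(D / k * (1 - decay**2))  # -> sqrt(2 D dt) as k -> 0
    center = np.zeros(2)
    pos = np.zeros((n, 2))
    pos[0] = center + rng.normal(0.0, np.sqrt(D / k), 2)
    p_hop = 1 - np.exp(-config.hop_rate * dt)
    for i in range(n - 1):
        if rng.random() < p_hop:
            theta = rng.uniform(0, 2 * np.pi)
            center = center + config.hop_size * np.array([np.cos(theta), np.sin(theta)])
        pos[i + 1] = center + (pos[i] - center) * decay + rng.normal(0.0, kick_sd, 2)
    return VertexTrack(vertex_id, t, pos, frame_interval=dt)


# ---------------------------------------------------------------------------
# Junction recordings via the two-vertex model
# ---------------------------------------------------------------------------

def _symmetric_params() -> ModelParams:
    """Passive-like pair: equal small viscoelastic parameter, piston disengaged."""
    return ModelParams(
        k_L=0.1, gamma_L=10.0, k_R=0.1, gamma_R=10.0,
        contraction_fraction=0.0, k_T_L=0.05, k_T_R=0.05,
    )


def gen_shortening_event(
    config: GeneratorConfig, asymmetric: bool = True, seed: int | None = None
) -> JunctionRecording:
    """A junction recording produced by the two-vertex viscoelastic model.

    ``asymmetric=True`` uses the default asymmetric parameters (stiff active
    side, compliant passive side, piston engaged) and yields a shortening
    junction with active/passive structure; ``asymmetric=False`` uses a
    symmetric passive-like pair with the piston disengaged (non-shortening
    regime). The 1D model coordinates are embedded along x with the model's
    transverse OU coordinates as y, sampled at the config frame interval.
    """
    base = ModelParams() if asymmetric else _symmetric_params()
    params = replace(base, T_max=config.duration,
                     seed=config.seed if seed is None else seed)
    result = simulate_junction(params, transverse=True)
    stride = max(1, int(round(config.frame_interval / params.dt)))
    idx = np.arange(0, result.times.size, stride)
    t = result.times[idx]
    pos_a = np.column_stack([result.x_L[idx], result.y_L[idx]])
    pos_b = np.column_stack([result.x_R[idx], result.y_R[idx]])
    label = "asymmetric" if asymmetric else "symmetric"
    return JunctionRecording(
        junction_id=f"sim-{label}-{params.seed}",
        vertex_a=VertexTrack("L", t, pos_a, config.frame_interval),
        vertex_b=VertexTrack("R", t, pos_b, config.frame_interval),
        condition_label=label,
    )


# ---------------------------------------------------------------------------
# Intensity-profile generators
# ---------------------------------------------------------------------------

def _render_clustered_frame(
    rng: np.random.Generator,
    x: np.ndarray,
    config: GeneratorConfig,
    scale: float | None = None,
    end_scales: tuple[float, float] | None = None,
) -> np.ndarray:
    """One frame of sharp-edged clusters at quasi-regular spacing plus noise.

    Clusters are boxcar occupancy domains (mean width = the local cluster
    scale, i.e. the FWHM after optical blur) with dispersed widths and
    brightnesses, convolved with a Gaussian PSF. Sharp cluster edges give the
    near-linear initial correlation decay that an exponential fits well —
    the signature of regularly ordered clusters — whereas smooth Gaussian
    bumps would give a band-limited (flat-topped) correlation. The whole
    geometry (width and spacing) scales with the local cluster scale, so the
    autocorrelation readout responds linearly to modulation. ``end_scales``
    imposes a linear gradient of the scale along the junction (for
    vertex-proximal sizing tests).
    """
    L = x[-1] - x[0]
    base = config.cluster_length_scale
    ratio = config.cluster_spacing / base  # spacing per unit scale

    def local_scale(pos: float) -> float:
        if end_scales is not None:
            f = np.clip((pos - x[0]) / L, 0.0, 1.0)
            return end_scales[0] * (1 - f) + end_scales[1] * f
        return scale if scale is not None else base

    # march cluster centers from a random phase before the junction start
    s0 = local_scale(x[0])
    c = x[0] - ratio * s0 + rng.uniform(0, ratio * s0)
    I = np.zeros_like(x)
    while c < x[-1] + ratio * local_scale(x[-1]):
        sc = local_scale(c)
        width = sc * max(0.3, 1.0 + rng.normal(0.0, config.width_jitter))
        amp = config.cluster_amplitude * max(
            0.1, 1.0 + rng.normal(0.0, config.amplitude_jitter)
        )
        I[np.abs(x - c) <= width / 2] += amp
        c = c + ratio * sc * (1 + rng.normal(0.0, config.spacing_jitter))
    px = x[1] - x[0]
    if config.psf_sigma > 0:
        I = gaussian_filter1d(I, config.psf_sigma / px, mode="nearest")
    if config.noise_sd > 0:
        I = I + rng.normal(0.0, config.noise_sd, x.size)
    return I


def _render_diffuse_frame(
    rng: np.random.Generator, x: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    """Cluster-free signal: near-uniform intensity with only large-scale variation.

    The envelope is much broader than the junction, so within the line of
    interest the fluctuations are dominated by pixel noise with a weak smooth
    trend — no characteristic length scale, no exponential correlation decay.
    """
    L = x[-1] - x[0]
    center = x[0] + L * rng.uniform(-0.25, 1.25)
    width = L * rng.uniform(2.0, 3.5)
    I = config.cluster_amplitude * np.exp(
        -((x - center) ** 2) / (2 * (width / 2.355) ** 2)
    )
    if config.noise_sd > 0:
        I = I + rng.normal(0.0, config.noise_sd, x.size)
    return I


def gen_clustered_profile_series(
    config: GeneratorConfig,
    regime: str = "clustered",
    n_frames: int | None = None,
    scale_series: np.ndarray | None = None,
    end_scales: tuple[float, float] | None = None,
    junction_id: str | None = None,
    stream: int = 3,
) -> IntensityProfileSeries:
    """Per-frame intensity profiles: ordered cluster trains or diffuse signal.

    ``regime='clustered'`` renders Gaussian bumps (FWHM = cluster scale) at
    quasi-regular spacing with ~10% jitter; ``'diffuse'`` renders a single
    broad envelope (the cis-clustering-deficient phenotype). ``scale_series``
    modulates the cluster scale per frame; ``end_scales`` imposes a scale
    gradient along the junction.
    """
    if regime not in ("clustered", "diffuse"):
        raise ValueError("regime must be 'clustered' or 'diffuse'")
    rng = _rng(config, stream)
    x = np.arange(0.0, config.junction_length + config.pixel_size / 2, config.pixel_size)
    if n_frames is None:
        n_frames = config.n_frames if scale_series is None else len(scale_series)
    if scale_series is not None and len(scale_series) != n_frames:
        raise ValueError("scale_series length must equal n_frames")
    times = config.frame_interval * np.arange(n_frames)
    frames = np.empty((n_frames, x.size))
    for i in range(n_frames):
        if regime == "diffuse":
            frames[i] = _render_diffuse_frame(rng, x, config)
        else:
            sc = None if scale_series is None else float(scale_series[i])
            frames[i] = _render_clustered_frame(rng, x, config, sc, end_scales)
    vertices = np.tile([x[0], x[-1]], (n_frames, 1))
    return IntensityProfileSeries(
        junction_id=junction_id or f"synth-{regime}",
        times=times,
        arc_positions=x,
        profiles=frames,
        vertex_positions=vertices,
        pixel_size=config.pixel_size,
    )


# ---------------------------------------------------------------------------
# Coupled length / cluster-size series
# ---------------------------------------------------------------------------

def gen_coupled_series(
    config: GeneratorConfig,
    onsets: tuple[float, ...] | None = None,
    junction_id: str = "coupled",
    stream: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, IntensityProfileSeries]:
    """Coupled junction shortening and cluster-size pulses with a programmed lead.

    The length series is a staircase: raised-cosine drops of ``pulse_drop``
    μm and duration ``pulse_duration`` at the given onsets (default: three
    onsets drawn in [80, 130], [200, 250] and [320, 370] s, matching the
    several pulses per ~400 s seen in pulsatile shortening traces), plus
    measurement noise. The cluster length scale is modulated by Gaussian
    pulses of amplitude ``cluster_pulse_amplitude`` centered ``lead_time`` s
    *before* each onset, and intensity frames are rendered from that scale
    series — so recovering the lead from the rendered profiles is a true
    end-to-end test, not circular smoothing.

    Returns ``(t, length_series, true_scale_series, profile_series)``.
    """
    rng = _rng(config, stream)
    t = config.time_grid()
    if onsets is None:
        onsets = (
            float(rng.uniform(80.0, 130.0)),
            float(rng.uniform(200.0, 250.0)),
            float(rng.uniform(320.0, 370.0)),
        )
    onsets = tuple(sorted(onsets))
    gaps = np.diff((0.0,) + onsets)
    if np.any(gaps <= config.lead_time):
        raise ValueError("lead_time must be smaller than the spacing between pulses")
    L0 = config.junction_length - 2.0  # leave arc margin at the vertices
    L = np.full(t.size, L0)
    scale = np.full(t.size, config.cluster_length_scale)
    for T0 in onsets:
        frac = np.clip((t - T0) / config.pulse_duration, 0.0, 1.0)
        L = L - config.pulse_drop * (1 - np.cos(np.pi * frac)) / 2
        peak_time = T0 - config.lead_time
        scale = scale + config.cluster_pulse_amplitude * np.exp(
            -((t - peak_time) ** 2) / (2 * config.cluster_pulse_sd**2)
        )
    if config.length_noise_sd > 0:
        L = L + rng.normal(0.0, config.length_noise_sd, t.size)
    profiles = gen_clustered_profile_series(
        config, "clustered", n_frames=t.size, scale_series=scale,
        junction_id=junction_id, stream=stream + 1000,
    )
    return t, L, scale, profiles
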