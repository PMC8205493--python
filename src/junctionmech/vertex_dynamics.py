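"""Glassy-dynamics statistics of tricellular-vertex motion.

During convergent extension, the two vertices bounding a shortening junction
behave asymmetrically: one ("active") moves persistently toward the other
("passive"), which stays caged like a particle in a dense glassy medium. The
estimators here quantify that contrast: the activity parameter A, the
time-averaged mean squared displacement and its log-log exponent, the Van
Hove displacement distribution with its non-Gaussian parameter, the velocity
autocorrelation, and the ensemble self-overlap Q(t) with the four-point
susceptibility chi4(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .tracks_io import JunctionRecording, ValidationError, VertexTrack

#: Default overlap cutoff a (μm) — order of the localization noise.
DEFAULT_CUTOFF_A = 0.2

#: Default MSD power-law fit range, in frames (inclusive): excludes the
#: localization-noise-dominated first lag and statistics-poor long lags.
DEFAULT_FIT_FRAMES = (2, 10)


class MsdRegime(str, Enum):
    SUPERDIFFUSIVE = "superdiffusive"
    SUBDIFFUSIVE_CAGED = "subdiffusive_caged"
    DIFFUSIVE = "diffusive"


class DisplacementComponent(str, Enum):
    INLINE = "inline"
    TRANSVERSE = "transverse"
    BOTH_POOLED = "both_pooled"


@dataclass(frozen=True)
class ActivityResult:
    """Per-vertex activity A = net displacement / initial junction length."""

    activity_a: float
    activity_b: float
    active_vertex_id: str
    passive_vertex_id: str
    tie: bool = False


@dataclass(frozen=True)
class MsdCurve:
    lags: np.ndarray          # s, starting at 0
    msd: np.ndarray           # μm^2
    alpha: float              # log-log slope over fit_range
    fit_range: tuple[float, float]  # (s, s)


@dataclass(frozen=True)
class VanHoveResult:
    lag: float
    bin_centers: np.ndarray   # μm
    density: np.ndarray       # 1/μm
    non_gaussian_alpha2: float
    n_samples: int


@dataclass(frozen=True)
class OverlapResult:
    times: np.ndarray         # s
    Q: np.ndarray             # in [0, 1]
    chi4: np.ndarray          # >= 0
    cutoff_a: float           # μm
    ensemble_size: int


def _require_uniform(track: VertexTrack) -> float:
    if not track.is_uniform():
        raise ValidationError(
            "track is not uniformly sampled; apply resample_uniform first"
        )
    return float(track.times[1] - track.times[0])


def activity_parameter(rec: JunctionRecording) -> ActivityResult:
    """Activity A of both vertices of a junction; larger-A vertex is 'active'.

    A is the ratio of the net (straight-line start-to-end) distance moved by
    a vertex to the initial junction length, evaluated in a fixed coordinate
    system. Ties go to vertex_a with ``tie=True``.
    """
    L0 = rec.initial_length
    a_val = rec.vertex_a.net_displacement() / L0
    b_val = rec.vertex_b.net_displacement() / L0
    tie = bool(np.isclose(a_val, b_val, rtol=0.0, atol=1e-12))
    if b_val > a_val and not tie:
        active, passive = rec.vertex_b.vertex_id, rec.vertex_a.vertex_id
    else:
        active, passive = rec.vertex_a.vertex_id, rec.vertex_b.vertex_id
    return ActivityResult(a_val, b_val, active, passive, tie)


def mean_squared_displacement(
    track: VertexTrack,
    max_lag: float | None = None,
    fit_frames: tuple[int, int] = DEFAULT_FIT_FRAMES,
) -> MsdCurve:
    """Time-averaged MSD(Δ) = <|r(t+Δ) − r(t)|²>_t with a log-log slope fit.

    ``max_lag`` (s) defaults to half the track span. The exponent alpha is
    the least-squares slope of log MSD vs log lag over ``fit_frames``
    (inclusive frame lags), clipped to the available lags.
    """
    dt = _require_uniform(track)
    span = track.times[-1] - track.times[0]
    if max_lag is None:
        max_lag = span / 2
    if max_lag > span / 2 + 1e-9:
        raise ValueError("max_lag must not exceed half the track span")
    n_lags = int(np.floor(max_lag / dt))
    pos = track.positions
    msd = np.zeros(n_lags + 1)
    for k in range(1, n_lags + 1):
        d = pos[k:] - pos[:-k]
        msd[k] = np.mean(np.sum(d * d, axis=1))
    lags = dt * np.arange(n_lags + 1)

    lo = max(1, fit_frames[0])
    hi = min(n_lags, fit_frames[1])
    alpha = np.nan
    if hi > lo:
        sel = slice(lo, hi + 1)
        with np.errstate(divide="ignore"):
            x = np.log(lags[sel])
            y = np.log(msd[sel])
        ok = np.isfinite(y)
        if ok.sum() >= 2:
            alpha = float(np.polyfit(x[ok], y[ok], 1)[0])
    return MsdCurve(lags, msd, alpha, (lo * dt, hi * dt))


def local_loglog_slopes(curve: MsdCurve) -> np.ndarray:
    """Centered finite-difference slopes of log MSD vs log lag (lag > 0)."""
    with np.errstate(divide="ignore"):
        x = np.log(curve.lags[1:])
        y = np.log(curve.msd[1:])
    ok = np.isfinite(y)
    slopes = np.full(y.size, np.nan)
    if ok.sum() >= 3:
        slopes[ok] = np.gradient(y[ok], x[ok])
    return slopes


def classify_msd_regime(curve: MsdCurve, delta: float = 0.1) -> MsdRegime:
    """Superdiffusive (alpha > 1+δ), caged (intermediate-lag slope < 1−δ), else diffusive.

    The caging signature is an intermediate-time slowdown of the MSD. To keep
    the call robust against the statistical noise of per-lag slopes, the
    local exponent is measured as a least-squares slope over sliding decade
    windows [k, 10k] of frame lags, starting just above the first lag (where
    a confinement plateau appears) and capped at n_lags/10 (beyond which the
    time-averaged MSD itself is too noisy for slope estimates); the minimum
    decade slope below 1−δ flags caging. Degenerate curves (too few lags,
    zero MSD) are diffusive.
    """
    if curve.lags.size < 7 or not np.isfinite(curve.alpha):
        return MsdRegime.DIFFUSIVE
    if curve.alpha > 1 + delta:
        return MsdRegime.SUPERDIFFUSIVE
    n_lags = curve.lags.size - 1
    k_cap = max(20, n_lags // 10)
    with np.errstate(divide="ignore"):
        logs = np.log(curve.lags[1:])
        logm = np.log(curve.msd[1:])
    min_slope = np.inf
    k = 2
    while 10 * k <= min(n_lags, k_cap):
        sel = (np.arange(1, n_lags + 1) >= k) & (np.arange(1, n_lags + 1) <= 10 * k)
        ok = sel & np.isfinite(logm)
        if ok.sum() >= 4:
            slope = np.polyfit(logs[ok], logm[ok], 1)[0]
            min_slope = min(min_slope, slope)
        k = max(k + 1, int(round(k * np.sqrt(10))))
    if np.isfinite(min_slope) and min_slope < 1 - delta:
        return MsdRegime.SUBDIFFUSIVE_CAGED
    return MsdRegime.DIFFUSIVE


def van_hove(
    tracks: Sequence[VertexTrack],
    lag: float,
    component: DisplacementComponent | str = DisplacementComponent.BOTH_POOLED,
    bins: int = 41,
    min_samples: int = 200,
) -> VanHoveResult:
    """Distribution of 1D displacement components over a fixed lag.

    Tracks are assumed to be expressed in the coordinate system of interest:
    ``inline`` takes the first coordinate, ``transverse`` the second, and
    ``both_pooled`` pools both. alpha2 = <δ⁴>/(3<δ²>²) − 1 is the 1D
    non-Gaussian parameter (0 for Gaussian displacements).
    """
    component = DisplacementComponent(component)
    deltas = []
    for track in tracks:
        dt = _require_uniform(track)
        k = int(round(lag / dt))
        if k < 1 or k >= track.n_frames:
            continue
        d = track.positions[k:] - track.positions[:-k]
        if component is DisplacementComponent.INLINE:
            deltas.append(d[:, 0])
        elif component is DisplacementComponent.TRANSVERSE:
            deltas.append(d[:, 1])
        else:
            deltas.append(d.ravel())
    pooled = np.concatenate(deltas) if deltas else np.empty(0)
    if pooled.size < min_samples:
        raise ValidationError(
            f"van_hove needs >= {min_samples} displacement samples, got {pooled.size}"
        )
    hist, edges = np.histogram(pooled, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # renormalize so the trapezoid integral over bin centers is exactly 1
    area = np.trapezoid(hist, centers)
    if area > 0:
        hist = hist / area
    m2 = np.mean(pooled**2)
    m4 = np.mean(pooled**4)
    alpha2 = float(m4 / (3 * m2**2) - 1) if m2 > 0 else 0.0
    return VanHoveResult(float(lag), centers, hist, alpha2, int(pooled.size))


def velocity_autocorrelation(track: VertexTrack, max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized velocity autocorrelation C_v(τ) with C_v(0) = 1.

    Velocities are frame-to-frame displacements divided by dt; the
    correlation is averaged over start times and normalized by <v·v>.
    Returns ``(lag_times, C_v)``.
    """
    dt = _require_uniform(track)
    v = np.diff(track.positions, axis=0) / dt
    n = v.shape[0]
    n_lags = min(int(np.floor(max_lag / dt)), n - 1)
    denom = np.mean(np.sum(v * v, axis=1))
    if denom <= 0:
        raise ValidationError("track has zero velocity; autocorrelation undefined")
    cv = np.ones(n_lags + 1)
    for k in range(1, n_lags + 1):
        cv[k] = np.mean(np.sum(v[:-k] * v[k:], axis=1)) / denom
    return dt * np.arange(n_lags + 1), cv


def self_overlap(
    tracks: Sequence[VertexTrack],
    cutoff_a: float = DEFAULT_CUTOFF_A,
    window: float | None = None,
    min_tracks: int = 5,
) -> OverlapResult:
    """Ensemble self-overlap Q(t) and four-point susceptibility chi4(t).

    For each start time t0 and track i, the overlap indicator q_i(t; t0) is 1
    when the vertex has moved less than ``cutoff_a`` between t0 and t0+t.
    Q(t) averages q over tracks and start times. chi4(t) = N·Var_t0[Q_w(t; t0)]
    where Q_w is the per-start-time ensemble mean over the N tracks: the
    variance of the instantaneous ensemble overlap measures how cooperatively
    the ensemble rearranges (dynamic heterogeneity).

    All tracks must share an identical uniform time base. ``window`` is the
    largest lag t reported (default: half the span).
    """
    if len(tracks) < min_tracks:
        raise ValidationError(f"self_overlap needs >= {min_tracks} tracks")
    dt = _require_uniform(tracks[0])
    t0s = tracks[0].times
    for track in tracks[1:]:
        if track.n_frames != tracks[0].n_frames or not np.allclose(track.times, t0s):
            raise ValidationError("all tracks must share the same time base")
    n = tracks[0].n_frames
    span = t0s[-1] - t0s[0]
    if window is None:
        window = span / 2
    n_lags = min(int(np.floor(window / dt)), n - 1)
    pos = np.stack([track.positions for track in tracks])  # (N, n, 2)
    N = pos.shape[0]
    Q = np.ones(n_lags + 1)
    chi4 = np.zeros(n_lags + 1)
    for k in range(1, n_lags + 1):
        disp = np.linalg.norm(pos[:, k:, :] - pos[:, :-k, :], axis=2)  # (N, n-k)
        q = (disp < cutoff_a).astype(float)
        Qw = q.mean(axis=0)          # ensemble mean per start time
        Q[k] = float(Qw.mean())
        chi4[k] = float(N * Qw.var())
    return OverlapResult(dt * np.arange(n_lags + 1), Q, chi4, float(cutoff_a), N)
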