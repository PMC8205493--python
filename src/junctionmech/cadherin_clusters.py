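"""Spatial and temporal correlation analysis of cadherin clustering along junctions.

Cadherins aggregate laterally (cis-clustering) into ~μm-scale clusters along
cell–cell junctions. Regularly ordered clusters produce a spatial
autocorrelation of the intensity fluctuations that decays (approximately
exponentially) and crosses zero at a distance set by the cluster scale; a
diffuse, cluster-free distribution does not. This module computes that
autocorrelation, extracts cluster sizes (zero crossing r0, exponential decay
length λ, or supra-threshold run lengths), classifies spatial order, sizes
clusters in the regions abutting each vertex during shortening pulses, and
relates cluster-size time series to junction shortening via lagged
cross-correlation and event-triggered averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .relaxation_analysis import PulseSet
from .tracks_io import IntensityProfileSeries, ValidationError

logger = logging.getLogger("junctionmech")

#: Default exponential-fit upper range (μm).
DEFAULT_FIT_RMAX = 2.0

#: Default goodness-of-fit threshold for the ordered/diffuse call.
DEFAULT_R2_THRESHOLD = 0.9

#: Default vertex-proximal region (μm).
DEFAULT_VERTEX_REGION = 3.0

#: Event-triggered window (s) preceding pulse onsets searched for the peak.
EVENT_WINDOW = 60.0

#: Post-onset margin (s) included in event-triggered averages so a peak near
#: the onset is not truncated; the peak itself is searched pre-onset only.
EVENT_POST_WINDOW = 20.0


class SpatialOrder(str, Enum):
    ORDERED = "ordered"
    DIFFUSE = "diffuse"


class ClusterSizeMethod(str, Enum):
    AUTOCORR = "autocorr"
    RUN_THRESHOLD = "run_threshold"


@dataclass(frozen=True)
class AutocorrelationCurve:
    r: np.ndarray              # μm, lag distances from 0
    C: np.ndarray              # mean autocorrelation, C(0) = 1
    sd: np.ndarray             # per-lag SD over frames
    n_profiles: int
    zero_crossing: float | None   # r0, μm
    decay_length: float | None    # λ, μm
    fit_r2: float


@dataclass(frozen=True)
class ClusterSizeSeries:
    times: np.ndarray
    mean_cluster_size: np.ndarray  # μm, NaN where undefined
    method: ClusterSizeMethod


@dataclass(frozen=True)
class CrossCorrelationResult:
    lags: np.ndarray           # s; negative lag = cluster signal leads
    rho: np.ndarray            # Pearson coefficients
    peak_lag: float            # lag of max |rho|
    event_triggered_lead: float | None  # s, None if no pulses given


def intensity_fluctuations(
    profile: np.ndarray, detrend: bool = False
) -> tuple[np.ndarray, bool]:
    """Mean-subtracted (optionally linearly detrended) intensity fluctuations.

    Returns ``(delta_I, flat)``; ``flat`` flags a constant profile whose
    autocorrelation is undefined.
    """
    I = np.asarray(profile, dtype=float)
    if I.size < 16:
        raise ValidationError("profile must have >= 16 samples")
    if detrend:
        x = np.arange(I.size, dtype=float)
        slope, intercept = np.polyfit(x, I, 1)
        dI = I - (slope * x + intercept)
    else:
        dI = I - I.mean()
    flat = bool(np.allclose(dI, 0.0))
    return dI, flat


def _single_frame_autocorr(dI: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased estimator: overlap sums / n, normalized by full-profile variance."""
    n = dI.size
    var = np.mean(dI * dI)
    C = np.empty(n_lags)
    for k in range(n_lags):
        C[k] = np.sum(dI[: n - k] * dI[k:]) / n / var
    return C


def _interp_zero_crossing(r: np.ndarray, C: np.ndarray) -> float | None:
    neg = np.where(C <= 0)[0]
    if neg.size == 0:
        return None
    i = int(neg[0])
    if i == 0:
        return 0.0
    return float(r[i - 1] + (r[i] - r[i - 1]) * C[i - 1] / (C[i - 1] - C[i]))


def spatial_autocorrelation(
    profiles: np.ndarray | IntensityProfileSeries | Sequence[np.ndarray],
    pixel_size: float | None = None,
    max_r: float | None = None,
    fit_rmax: float = DEFAULT_FIT_RMAX,
) -> AutocorrelationCurve:
    """Mean spatial autocorrelation C(r) of intensity fluctuations over frames.

    Each frame is mean-subtracted and normalized by its own full-profile
    variance (biased estimator, so |C| ≤ 1 and C(0) = 1 exactly), then
    averaged across frames with a per-lag SD. ``max_r`` defaults to half the
    profile span. The first zero crossing r0 is linearly interpolated;
    λ and fit_r2 come from :func:`cluster_size_exponential_fit`. Constant
    frames are skipped (logged); if all frames are constant this is an error.
    """
    if isinstance(profiles, IntensityProfileSeries):
        pixel_size = profiles.pixel_size
        frames = profiles.profiles
    else:
        frames = np.atleast_2d(np.asarray(profiles, dtype=float))
    if pixel_size is None:
        raise ValueError("pixel_size is required for raw profile input")
    n_px = frames.shape[1]
    span = (n_px - 1) * pixel_size
    if max_r is None:
        max_r = span / 2
    if max_r > span / 2 + 1e-9:
        raise ValueError("max_r must not exceed half the profile span")
    n_lags = int(np.floor(max_r / pixel_size)) + 1
    curves = []
    skipped = 0
    for frame in frames:
        dI, flat = intensity_fluctuations(frame)
        if flat:
            skipped += 1
            continue
        curves.append(_single_frame_autocorr(dI, n_lags))
    if skipped:
        logger.info("spatial_autocorrelation: skipped %d constant frames", skipped)
    if not curves:
        raise ValidationError("all frames are constant; autocorrelation undefined")
    stack = np.stack(curves)
    C = stack.mean(axis=0)
    sd = stack.std(axis=0)
    r = pixel_size * np.arange(n_lags)
    r0 = _interp_zero_crossing(r, C)
    lam, r2 = cluster_size_exponential_fit(r, C, r0=r0, fit_rmax=fit_rmax)
    return AutocorrelationCurve(r, C, sd, len(curves), r0, lam, r2)


def cluster_size_exponential_fit(
    r: np.ndarray,
    C: np.ndarray,
    r0: float | None = None,
    fit_rmax: float = DEFAULT_FIT_RMAX,
) -> tuple[float | None, float]:
    """Fit C(r) = exp(−r/λ) on r ∈ [0, min(fit_rmax, r0)]; returns (λ, r²).

    Regularly ordered clusters give a near-exponential initial decay, so a
    high r² supports spatial order. Returns ``(None, 0.0)`` when the fit
    fails or has fewer than 5 lags of support.
    """
    upper = fit_rmax if r0 is None else min(fit_rmax, r0)
    mask = r <= upper + 1e-12
    if mask.sum() < 5:
        # widen minimally to 5 lags if available; otherwise flag failure
        if r.size < 5:
            return None, 0.0
        mask = np.zeros(r.size, dtype=bool)
        mask[:5] = True
    rr, cc = r[mask], C[mask]
    if np.all(cc <= 0):
        return None, 0.0
    try:
        popt, _ = curve_fit(
            lambda x, lam: np.exp(-x / lam), rr, cc, p0=[max(upper / 2, 1e-3)],
            bounds=(1e-6, 1e3), maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None, 0.0
    lam = float(popt[0])
    resid = cc - np.exp(-rr / lam)
    ss_tot = float(np.sum((cc - cc.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return lam, r2


def spatial_order_test(
    curve: AutocorrelationCurve, r2_threshold: float = DEFAULT_R2_THRESHOLD
) -> SpatialOrder:
    """Ordered iff the exponential fit is good (r² ≥ threshold) and C crosses zero."""
    if curve.fit_r2 >= r2_threshold and curve.zero_crossing is not None:
        return SpatialOrder.ORDERED
    return SpatialOrder.DIFFUSE


def cluster_size_series(
    series: IntensityProfileSeries,
    method: ClusterSizeMethod | str = ClusterSizeMethod.AUTOCORR,
) -> ClusterSizeSeries:
    """Per-frame mean cluster size (μm).

    ``autocorr``: each frame's autocorrelation zero crossing r0 (decay length
    λ as fallback when C never crosses zero). ``run_threshold``: clusters are
    maximal runs of pixels with I > mean + 1 SD; the size is the mean run
    length × pixel size. Frames with no measurable clusters yield NaN; if
    every frame is degenerate this is an error.
    """
    method = ClusterSizeMethod(method)
    if series.n_frames < 10:
        raise ValidationError("cluster_size_series needs >= 10 frames")
    sizes = np.full(series.n_frames, np.nan)
    for i, frame in enumerate(series.profiles):
        dI, flat = intensity_fluctuations(frame)
        if flat:
            continue
        if method is ClusterSizeMethod.AUTOCORR:
            n_lags = frame.size // 2
            C = _single_frame_autocorr(dI, n_lags)
            r = series.pixel_size * np.arange(n_lags)
            r0 = _interp_zero_crossing(r, C)
            if r0 is not None and r0 > 0:
                sizes[i] = r0
            else:
                lam, _ = cluster_size_exponential_fit(r, C, r0=r0)
                if lam is not None:
                    sizes[i] = lam
        else:
            thresh = frame.mean() + frame.std()
            above = frame > thresh
            runs = _run_lengths(above)
            if runs:
                sizes[i] = float(np.mean(runs)) * series.pixel_size
    if np.all(np.isnan(sizes)):
        raise ValidationError("all frames degenerate; no cluster sizes measurable")
    return ClusterSizeSeries(series.times.copy(), sizes, method)


def _run_lengths(mask: np.ndarray) -> list[int]:
    runs, count = [], 0
    for m in mask:
        if m:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def vertex_region_cluster_size(
    series: IntensityProfileSeries,
    pulses: PulseSet,
    region: float = DEFAULT_VERTEX_REGION,
) -> dict[str, float | None]:
    """Cluster size in the ~``region`` μm windows abutting each vertex,
    pooled over shortening-pulse frames.

    Returns ``{"vertex_a": size, "vertex_b": size}`` where size is the pooled
    window autocorrelation's zero crossing (decay length as fallback).
    Pooling over pulse frames stabilizes the short-window estimate.
    """
    if len(pulses) == 0:
        raise ValidationError("vertex_region_cluster_size requires pulses")
    n_region = int(round(region / series.pixel_size))
    if n_region < 10:
        raise ValidationError("vertex region shorter than 10 pixels")
    in_pulse = np.zeros(series.n_frames, dtype=bool)
    for start, end in pulses.intervals:
        in_pulse |= (series.times >= start) & (series.times <= end)
    if not np.any(in_pulse):
        raise ValidationError("no profile frames fall within the pulses")
    x = series.arc_positions
    out: dict[str, float | None] = {}
    for vi, name in ((0, "vertex_a"), (1, "vertex_b")):
        windows = []
        for fi in np.where(in_pulse)[0]:
            v = series.vertex_positions[fi, vi]
            other = series.vertex_positions[fi, 1 - vi]
            sign = 1.0 if other >= v else -1.0
            lo, hi = sorted((v, v + sign * region))
            mask = (x >= lo - 1e-9) & (x <= hi + 1e-9)
            if mask.sum() < n_region:
                raise ValidationError(
                    f"vertex region ({region} μm) exceeds the available junction span"
                )
            windows.append(series.profiles[fi, mask][:n_region])
        curve = spatial_autocorrelation(np.stack(windows), series.pixel_size)
        out[name] = curve.zero_crossing if curve.zero_crossing else curve.decay_length
    return out


def length_cluster_crosscorrelation(
    length_series: np.ndarray,
    cluster_sizes: np.ndarray,
    t_grid: np.ndarray,
    max_lag: float = 100.0,
    pulses: PulseSet | None = None,
    min_overlap: int = 20,
    event_window: float = EVENT_WINDOW,
) -> CrossCorrelationResult:
    """Lagged Pearson correlation rho(ℓ) between cluster size s(t) and length L(t+ℓ).

    Negative lags mean the cluster signal leads the length signal. Lags with
    fewer than ``min_overlap`` overlapping finite frames are dropped. When
    ``pulses`` is given, the event-triggered lead is also computed: s(t) is
    averaged in windows aligned to pulse onsets and the lead is the onset
    time minus the time of the pre-onset maximum within [−event_window, 0].
    """
    L = np.asarray(length_series, dtype=float)
    s = np.asarray(cluster_sizes, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if L.shape != s.shape or L.shape != t.shape:
        raise ValueError("length, cluster and time series must share a grid")
    dt = float(np.median(np.diff(t)))
    if np.any(np.abs(np.diff(t) - dt) > 1e-6 * dt):
        raise ValidationError("cross-correlation requires a uniform time base")
    max_k = int(np.floor(max_lag / dt))
    lags, rhos = [], []
    for k in range(-max_k, max_k + 1):
        if k >= 0:
            a, b = s[: L.size - k] if k else s, L[k:]
        else:
            a, b = s[-k:], L[:k]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_overlap:
            continue
        if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            continue
        rhos.append(float(pearsonr(a[ok], b[ok])[0]))
        lags.append(k * dt)
    if not rhos:
        raise ValidationError("insufficient overlap at every lag")
    lags_arr = np.asarray(lags)
    rho_arr = np.asarray(rhos)
    peak = float(lags_arr[int(np.argmax(np.abs(rho_arr)))])
    lead = None
    if pulses is not None and len(pulses) > 0:
        lead = event_triggered_lead(s, t, pulses, event_window)
    return CrossCorrelationResult(lags_arr, rho_arr, peak, lead)


def _collect_onset_windows(
    s: np.ndarray, t: np.ndarray, pulses: PulseSet, dt: float,
    event_window: float, post_window: float,
) -> list[np.ndarray]:
    nl = int(round(event_window / dt))
    nr = int(round(post_window / dt))
    segments = []
    for onset in pulses.onsets:
        i0 = int(round((onset - t[0]) / dt))
        if i0 - nl < 0 or i0 + nr >= s.size:
            continue
        segments.append(s[i0 - nl : i0 + nr + 1])
    return segments


def _peak_lead_from_average(avg: np.ndarray, dt: float, nl: int) -> float | None:
    """Pre-onset peak location by half-prominence centroid.

    The pooled average is lightly smoothed (3-bin moving mean), the maximum
    is located among pre-onset lags, and the peak position is refined as the
    intensity-weighted centroid of the contiguous region above half the
    peak's prominence over the window median — robust to single-bin noise
    spikes and to the flat top of a broad peak.
    """
    if np.all(np.isnan(avg)):
        return None
    avg = np.convolve(np.pad(avg, 1, mode="edge"), np.ones(3) / 3, mode="valid")
    tau = dt * np.arange(-nl, avg.size - nl)
    pre = tau <= 0
    masked = np.where(pre, avg, -np.inf)
    i = int(np.nanargmax(masked))
    baseline = float(np.nanmedian(avg))
    prominence = avg[i] - baseline
    if not np.isfinite(prominence) or prominence <= 0:
        return float(-tau[i])
    level = baseline + prominence / 2
    lo = i
    while lo > 0 and avg[lo - 1] >= level:
        lo -= 1
    hi = i
    while hi < avg.size - 1 and avg[hi + 1] >= level:
        hi += 1
    weights = avg[lo : hi + 1] - baseline
    return float(-np.sum(tau[lo : hi + 1] * weights) / np.sum(weights))


def event_triggered_lead(
    cluster_sizes: np.ndarray,
    t_grid: np.ndarray,
    pulses: PulseSet,
    event_window: float = EVENT_WINDOW,
    post_window: float = EVENT_POST_WINDOW,
) -> float | None:
    """Lead time (s) by which the onset-aligned mean cluster signal peaks
    before pulse onsets; None when no complete onset window exists."""
    s = np.asarray(cluster_sizes, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    dt = float(np.median(np.diff(t)))
    segments = _collect_onset_windows(s, t, pulses, dt, event_window, post_window)
    if not segments:
        return None
    avg = np.nanmean(np.stack(segments), axis=0)
    return _peak_lead_from_average(avg, dt, int(round(event_window / dt)))


def pooled_event_triggered_lead(
    cluster_series: Sequence[np.ndarray],
    time_grids: Sequence[np.ndarray],
    pulse_sets: Sequence[PulseSet],
    event_window: float = EVENT_WINDOW,
    post_window: float = EVENT_POST_WINDOW,
) -> float | None:
    """Lead time from the event-triggered average pooled over many junctions.

    All onset-aligned windows from every junction are averaged into one grand
    mean before locating the pre-onset peak — the multi-junction analogue of
    :func:`event_triggered_lead`, far more stable when each junction carries
    only a handful of pulses.
    """
    segments = []
    dt_ref = None
    for s, t, pulses in zip(cluster_series, time_grids, pulse_sets):
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=float)
        dt = float(np.median(np.diff(t)))
        if dt_ref is None:
            dt_ref = dt
        elif abs(dt - dt_ref) > 1e-9:
            raise ValidationError("all junctions must share the frame interval")
        segments.extend(
            _collect_onset_windows(s, t, pulses, dt, event_window, post_window)
        )
    if not segments or dt_ref is None:
        return None
    avg = np.nanmean(np.stack(segments), axis=0)
    return _peak_lead_from_average(avg, dt_ref, int(round(event_window / dt_ref)))


def crosscorrelation_matrix(
    results: dict[str, CrossCorrelationResult]
) -> pd.DataFrame:
    """Assemble per-junction cross-correlation rows into a long table for heatmaps."""
    rows = []
    for junction_id, res in results.items():
        for lag, rho in zip(res.lags, res.rho):
            rows.append((junction_id, lag, rho))
    return pd.DataFrame(rows, columns=["junction_id", "lag_s", "rho"])
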