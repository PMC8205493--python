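"""Junction-length relaxation analysis.

Shortening v-junctions relax in a self-similar way: after normalizing the
length change and rescaling time by a per-junction timescale τ, control
junctions collapse onto a single compressed-exponential master curve
Ln(s) = exp(−s^β) with β > 1. Junctions lacking mechanical heterogeneity
(non-shortening, cluster-disrupted) deviate from that master curve; the
deviation is quantified by the residue R. This module also detects the
pulsatile shortening episodes used to align cluster-size dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .tracks_io import JunctionRecording, ShorteningClass, ValidationError

#: Observation time scale (s) over which shortening is judged.
DEFAULT_T_OBS = 400.0

#: Minimum fractional length reduction to call a junction "shortening".
DEFAULT_MIN_FRACTION = 0.1

#: Moving-average window (s) used for smoothing length series.
DEFAULT_SMOOTHING_WINDOW = 10.0

#: Multi-start initial guesses for the stretching exponent.
BETA_STARTS = (0.5, 1.0, 1.5, 2.0, 3.0)
BETA_BOUNDS = (0.2, 5.0)

#: Rescaled-time domain over which the residue is evaluated.
RESIDUE_S_MAX = 3.0


@dataclass(frozen=True)
class RelaxationFit:
    tau: float                 # s
    beta: float                # dimensionless
    L_inf: float               # μm, plateau estimate
    times: np.ndarray          # s
    Ln_series: np.ndarray      # normalized length change
    rss: float                 # residual sum of squares of the fit
    converged: bool
    degenerate: bool = False   # L(0) <= L_inf: nothing to normalize

    @property
    def rescaled_times(self) -> np.ndarray:
        return self.times / self.tau

    @property
    def compressed(self) -> bool:
        return bool(self.converged and self.beta > 1.0)


@dataclass(frozen=True)
class PulseSet:
    """Disjoint, increasing pulsatile-shortening intervals and their onsets."""

    intervals: tuple[tuple[float, float], ...]
    smoothing_window: float
    rate_threshold: float

    @property
    def onsets(self) -> tuple[float, ...]:
        return tuple(start for start, _ in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def moving_average(values: np.ndarray, window: float, dt: float) -> np.ndarray:
    """Centered moving average with an odd window of ~``window`` seconds."""
    w = max(1, int(round(window / dt)))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return np.asarray(values, dtype=float)
    pad = w // 2
    padded = np.pad(np.asarray(values, dtype=float), pad, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(padded, kernel, mode="valid")


def classify_shortening(
    rec: JunctionRecording,
    T_obs: float = DEFAULT_T_OBS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW,
) -> ShorteningClass:
    """Classify a junction as shortening / non-shortening over ``T_obs``.

    Non-shortening junctions are defined by *net* change: if the smoothed
    length drops by less than ``min_fraction·L(0)`` between the start and
    T_obs the junction is non-shortening, regardless of transient dips.
    Otherwise it is shortening (a net reduction implies the transient
    minimum criterion, since min L ≤ final L). A recording shorter than
    ``T_obs`` is classified shortening if the criterion is already met
    within its span, and is otherwise unclassified (later shortening cannot
    be ruled out).
    """
    t = rec.times
    dt = float(np.median(np.diff(t)))
    L = moving_average(rec.length_series, smoothing_window, dt)
    mask = t - t[0] <= T_obs + 1e-9
    L0 = L[mask][0]
    net_reduction = L0 - L[mask][-1]
    if net_reduction >= min_fraction * L0:
        return ShorteningClass.SHORTENING
    if t[-1] - t[0] < T_obs:
        return ShorteningClass.UNCLASSIFIED
    return ShorteningClass.NON_SHORTENING


def normalized_length(
    length_series: np.ndarray, t_grid: np.ndarray, tail_fraction: float = 0.1
) -> tuple[np.ndarray, float, bool]:
    """Ln(t) = (L(t) − L_inf) / (L(0) − L_inf) with L_inf = mean of the final tail.

    Returns ``(Ln, L_inf, degenerate)``; degenerate marks L(0) ≤ L_inf
    (nothing relaxed — typical of non-shortening junctions), in which case
    Ln is still returned for residue computation but carries no collapse
    meaning.
    """
    L = np.asarray(length_series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if L.shape != t.shape:
        raise ValueError("length series and time grid must have equal shapes")
    n_tail = max(1, int(round(tail_fraction * L.size)))
    L_inf = float(np.mean(L[-n_tail:]))
    denom = L[0] - L_inf
    if denom <= 0:
        # fall back to a unit denominator scaled by L(0) to keep Ln finite
        return (L - L_inf) / max(L[0], 1e-12), L_inf, True
    return (L - L_inf) / denom, L_inf, False


def compressed_exponential(t: np.ndarray, tau: float, beta: float) -> np.ndarray:
    return np.exp(-np.power(np.maximum(t, 0.0) / tau, beta))


def fit_compressed_exponential(
    Ln_series: np.ndarray, t_grid: np.ndarray
) -> tuple[float, float, float, bool]:
    """Least-squares fit of Ln(t) = exp(−(t/τ)^β); returns (τ, β, rss, converged).

    β is constrained to (0.2, 5); the fit is restarted from several β
    guesses and the best residual wins. A fit that fails from every start
    returns ``converged=False`` with NaN parameters.
    """
    Ln = np.asarray(Ln_series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if Ln.size < 10:
        raise ValidationError("compressed-exponential fit needs >= 10 points")
    span = max(t[-1] - t[0], 1e-9)
    best: tuple[float, float, float] | None = None
    for beta0 in BETA_STARTS:
        try:
            popt, _ = curve_fit(
                compressed_exponential,
                t,
                Ln,
                p0=[span / 3, beta0],
                bounds=([1e-6, BETA_BOUNDS[0]], [1e6, BETA_BOUNDS[1]]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((compressed_exponential(t, *popt) - Ln) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), float(popt[1]), rss)
    if best is None:
        return float("nan"), float("nan"), float("nan"), False
    return best[0], best[1], best[2], True


def analyze_relaxation(rec: JunctionRecording) -> RelaxationFit:
    """Normalize a junction's length series and fit the compressed exponential."""
    t = rec.times - rec.times[0]
    Ln, L_inf, degenerate = normalized_length(rec.length_series, t)
    tau, beta, rss, converged = fit_compressed_exponential(Ln, t)
    if not converged:
        tau = max(t[-1] / 3, 1e-9)
    return RelaxationFit(tau, beta, L_inf, t, Ln, rss, converged, degenerate)


def universal_beta(fits: list[RelaxationFit]) -> float:
    """Ensemble master-curve exponent: median β of the converged fits."""
    betas = [f.beta for f in fits if f.converged and np.isfinite(f.beta)]
    if not betas:
        raise ValidationError("no converged fits to take the median over")
    return float(np.median(betas))


def relaxation_residue(
    fit: RelaxationFit, universal_beta: float, s_max: float = RESIDUE_S_MAX
) -> float:
    """Mean squared deviation of Ln from the master curve exp(−s^β̄) on s ∈ [0, s_max].

    Time is rescaled by the junction's own τ; the residue is zero iff the
    rescaled curve lies on the universal compressed exponential.
    """
    if not np.isfinite(fit.tau) or fit.tau <= 0:
        raise ValidationError("fit has no valid tau for rescaling")
    s = fit.rescaled_times
    mask = s <= s_max
    if not np.any(mask):
        raise ValidationError("no samples in the rescaled domain [0, s_max]")
    model = np.exp(-np.power(s[mask], universal_beta))
    return float(np.mean((fit.Ln_series[mask] - model) ** 2))


def detect_shortening_pulses(
    length_series: np.ndarray,
    t_grid: np.ndarray,
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW,
    rate_threshold: float | None = None,
    min_duration: float = 6.0,
) -> PulseSet:
    """Detect pulsatile-shortening intervals as sustained fast negative length rates.

    The length series is smoothed by a centered moving average; the rate is
    its centered finite difference. A pulse is a maximal interval with
    rate < −``rate_threshold`` lasting at least ``min_duration``. The default
    threshold is one robust SD of |rate| (MAD × 1.4826) — data-adaptive, so
    units and noise levels need no per-movie tuning.
    """
    L = np.asarray(length_series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    dt = float(np.median(np.diff(t)))
    if np.any(np.abs(np.diff(t) - dt) > 1e-6 * dt):
        raise ValidationError("pulse detection requires a uniform time grid")
    if t[-1] - t[0] < 3 * smoothing_window:
        raise ValidationError("series span must be at least 3x the smoothing window")
    Ls = moving_average(L, smoothing_window, dt)
    rate = np.gradient(Ls, t)
    if rate_threshold is None:
        abs_rate = np.abs(rate)
        mad = np.median(np.abs(abs_rate - np.median(abs_rate)))
        rate_threshold = 1.4826 * mad
    below = rate < -rate_threshold
    intervals: list[tuple[float, float]] = []
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if t[j - 1] - t[i] >= min_duration:
                intervals.append((float(t[i]), float(t[j - 1])))
            i = j
        else:
            i += 1
    return PulseSet(tuple(intervals), float(smoothing_window), float(rate_threshold))
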