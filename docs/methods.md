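# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `junctionmech`, and what the synthetic-data generators do and do not
establish.

## Conventions and units

Times are in seconds, lengths in micrometers, intensities in arbitrary
units. Vertex tracks are 2D (the imaging this package targets analyzes a
single z-plane). The nominal frame interval is 2 s; intensity profiles are
sampled at 0.1 μm/pixel (a stated default — the super-resolution pixel size
is configurable, not measured here). Track tables are long-format delimited
text; profile matrices have one row per frame with a header row of arc
positions and a sidecar table of per-frame vertex arc positions.

## Vertex dynamics

**Activity parameter.** A = ‖r(T) − r(0)‖ / L₀ per vertex, in a fixed
coordinate frame; "net distance" is the straight-line start-to-end
displacement, not the path length. The vertex with larger A is labeled
active; exact ties go to vertex_a and are flagged.

**MSD and exponent.** Time-averaged MSD(Δ) over all start times; α is the
least-squares slope of log MSD vs log Δ over frame lags 2–10 (default).
Lag 1 is excluded because localization noise dominates it; long lags are
excluded because the time average has too few independent samples.

**Regime classification.** Superdiffusive if α > 1.1. The caging call
looks for an intermediate-time slowdown: local exponents are measured as
least-squares slopes over sliding decade windows [k, 10k] of frame lags
(k from 2, windows capped at n_lags/10, advancing by √10); a minimum
decade slope below 0.9 flags `subdiffusive_caged`. Decade windows rather
than per-lag derivatives: the time-averaged MSD at long lags wanders
enough that raw local slopes of a genuinely Brownian track routinely dip
below 0.9, while decade-fit slopes do not. Degenerate curves (frozen
tracks, too few lags) fall back to `diffusive`.

**Van Hove.** Histogram density of 1D displacement components at a fixed
lag; tracks are assumed already expressed in the coordinate system of
interest (`inline` = first coordinate, `transverse` = second,
`both_pooled` pools both). The density is renormalized so its trapezoid
integral over bin centers is exactly 1. α₂ = ⟨δ⁴⟩/3⟨δ²⟩² − 1 is 0 for
Gaussian displacements and positive for the fat-tailed mixtures produced
by caged-with-hops dynamics.

**Self-overlap and χ₄.** q_i(t; t₀) = 1 if track i moved less than the
cutoff a between t₀ and t₀+t. Q(t) averages over tracks and start times.
χ₄(t) = N·Var_{t₀}[Q_w(t; t₀)] where Q_w is the per-start-time ensemble
mean: the variance of the instantaneous ensemble overlap, taken over start
times, measures how cooperatively the ensemble rearranges. This convention
(start-time moments of the ensemble-mean overlap) is declared here because
overlap estimators admit several normalizations; it satisfies χ₄ ≡ 0 for
an immobile ensemble and χ₄ ≥ 0 always. Default cutoff a = 0.2 μm (order
of localization noise); results should be reported across
a ∈ {0.1, 0.2, 0.4} μm when used comparatively.

## Transverse mechanics

**Decomposition.** Default `initial_axis`: û is the unit vector from this
vertex's initial position toward the other vertex's initial position, n̂
its +90° rotation, and displacements from the initial position are
projected onto (û, n̂). A fixed frame avoids feedback between shortening
and the axis definition; `instantaneous_axis` (per-frame û) is provided
for sensitivity analysis.

**Hop function.** For each window [t−W/2, t+W/2] split into halves H1, H2:
R_T(t) = [⟨(y−⟨y⟩_H2)²⟩_H1 ⟨(y−⟨y⟩_H1)²⟩_H2]^{1/4} with y the transverse
coordinate — the two-half form (in the style of cage-hop detectors) is
sensitive both to within-window spread and to shifts between the halves.
Default W = 20 s (10 frames). A plain windowed standard deviation is
available as `method="windowed_sd"`; both variants should be reported.
For stationary transverse motion R_T tracks the stationary spread, so
doubling an OU confinement rate at fixed driving noise reduces ⟨R_T⟩ by
√2 — the basis of the stiffness-proxy interpretation (proportionality
only; no absolute calibration is attempted).

**Straightness.** S = net displacement / path length ∈ [0, 1]; undefined
(flagged) for zero path length.

## Relaxation analysis

**Classification.** A junction is non-shortening when the smoothed length
(10 s centered moving average) shows a *net* reduction below 10% of L₀
over the 400 s observation window — net change is the defining quantity,
so transient dips that recover do not count as shortening. Since the
transient minimum is always at least the net reduction, the shortening
branch needs no separate dip test. Recordings shorter than 400 s classify
as shortening only if the criterion is already met within their span, and
are otherwise unclassified.

**Normalization and fit.** L_∞ is the mean of the final 10% of samples;
L_n(t) = (L − L_∞)/(L₀ − L_∞) guarantees L_n(0) = 1 and collapse onto
exp(−s^β) for ideal data, and is invariant under affine rescaling of L.
The compressed-exponential fit uses `scipy.optimize.curve_fit` with β
bounded to (0.2, 5) and multi-start over β₀ ∈ {0.5, 1, 1.5, 2, 3}; the
best residual wins. "Compressed" means β > 1.

**Residue.** With s = t/τ (per-junction τ) and β̄ the ensemble median β of
converged control fits, R = mean of (L_n(s) − exp(−s^β̄))² over s ∈ [0, 3].
Mean-square on a fixed rescaled domain is declared (not inferred): it is
zero iff the curve lies on the master curve and grows quadratically with
deviation. For degenerate (non-shortening) series the normalization
denominator falls back to L₀, leaving L_n as a fluctuation measure whose
residue is large — the intended contrast.

**Pulse detection.** Lengths are smoothed (centered moving average, 10 s),
the rate is the centered finite difference, and a pulse is a maximal run
of rate < −threshold lasting ≥ 6 s, with onset = run start. The default
threshold is one robust SD of |rate| (MAD × 1.4826) — data-adaptive, so
units and noise levels need no per-movie tuning. The symmetric smoothing
kernel advances detected onsets by up to half its support (~2 s net at
realistic noise); the event-triggered lead estimator absorbs most of this
(below), and the residual bias is within the frame interval.

## Two-vertex viscoelastic model

Overdamped (friction-dominated — no inertial term) dynamics of two vertex
positions x_L < x_R on a line:

    dx_i/dt = (k_i/γ_i)(rest_i(t) − x_i) + ζ_i(t)

with rest positions driven by a piston that contracts the rest length from
L₀ to (1−c)L₀ over t_p as min(t/t_p, 1)^ψ_i per side, and independent
stationary OU noises ζ_i (velocity units; sd σ_ζ, correlation time τ_c)
on both vertices. The concrete piston form (power-law approach, per-vertex
forces F_i = k_i(rest_i − x_i)) instantiates the verbal model description;
every constant is config-exposed. Noise is applied to both vertices with
identical (σ_ζ, τ_c) — asymmetry is carried by k/γ and ψ, which are the
swept axes.

Defaults: L₀ = 10 μm, c = 0.8, t_p = 300 s, T = 400 s, dt = 0.1 s,
ψ = 1.5, asymmetric viscoelastic parameters k_L/γ_L = 1 s⁻¹ and
k_R/γ_R = 10⁻² s⁻¹, σ_ζ = 0.01 μm/s, τ_c = 10 s. σ_ζ is not a measured
value; it was chosen so a passive-like vertex (k/γ = 10⁻² s⁻¹) has
stationary positional fluctuation ≈ 0.3 μm and a symmetric non-shortening
junction fluctuates by a few percent of L₀, and it was fixed before any
acceptance testing. c = 0 (piston disengaged) is allowed and is the
non-shortening regime: with any engaged piston, even k/γ = 10⁻³ s⁻¹
junctions creep past the 10% net-reduction bound within 400 s.

Integration is Euler–Maruyama; an explicit stability check requires dt ≤
(fastest timescale)/5. If a step makes x_R < x_L both are clamped to the
midpoint (length reflects at 0). With σ_ζ = 0 the integrator matches a
fine-step reference to better than 10⁻³ relative error at the default dt.
Optional transverse coordinates follow per-vertex OU processes with rates
k_T (default 0.2 s⁻¹ active side, 0.05 s⁻¹ passive side).

**Success rule.** A run succeeds when the smoothed length stays ≤ 0.33·L₀
for at least 10 s — T1 completion needs sustained near-zero length; the
hold rejects noise grazing. Sweeps report per-cell success fractions over
seeds on a default grid of k/γ ∈ logspace[10⁻³, 1] s⁻¹ (8 points) and
ψ ∈ [0.5, 2] (7 points). The scientifically meaningful outputs are regime
contrasts (symmetric-small fails, strongly asymmetric succeeds), not the
absolute coordinates of regime boundaries.

## Cadherin cluster analysis

**Autocorrelation.** Per frame, δI = I − ⟨I⟩ and C(r) = biased
autocovariance (overlap sums divided by n) normalized by the full-profile
variance, so C(0) = 1 and |C| ≤ 1; frames are averaged with per-lag SD
after per-frame normalization (robust to brightness differences across
frames). Cluster size is read out primarily as the first zero crossing r₀
(linear interpolation), with the exponential decay length λ (least-squares
fit of exp(−r/λ) on r ∈ [0, min(2 μm, r₀)]) and mean supra-threshold run
length (runs of I > mean + 1 SD) as cross-checks; all three are exposed.

**Spatial order.** `ordered` iff the exponential fit has r² ≥ 0.9 and a
zero crossing exists within the evaluated range. Regularly ordered,
sharp-edged clusters give a near-linear initial decay that the exponential
fits well; diffuse (cluster-free) signal leaves fluctuations dominated by
pixel noise over a weak large-scale trend, which the exponential cannot
fit. Note the rule is purely operational: profiles of pure white noise
formally pass it (nugget at r = 0, immediate crossing) — the classifier is
calibrated for the clustered-vs-diffuse contrast, not as a general test.

**Vertex-proximal sizing.** Profiles are restricted to the 3 μm arc
window adjacent to each vertex (per frame, toward the junction interior)
and pooled over shortening-pulse frames before autocorrelation — pooling
stabilizes the short-window estimate; r₀ (fallback λ) is the reported
size.

**Cross-correlation and lead.** rho(ℓ) is the Pearson correlation of
cluster size s(t) with length L(t+ℓ) at integer-frame lags (negative lag =
cluster leads); lags with fewer than 20 overlapping finite frames are
dropped. The event-triggered lead aligns s(t) windows at detected pulse
onsets (window −60 s to +20 s; the +20 s margin prevents truncation of a
near-onset peak), averages them — pooled across junctions in
`pooled_event_triggered_lead`, which is the estimator of record when
junctions carry only a few pulses — lightly smooths the average (3-bin
moving mean), locates the maximum among pre-onset lags, and refines the
peak position as the intensity-weighted centroid of the contiguous region
above half the peak's prominence over the window median. The centroid
makes the estimate robust to the flat top of a broad peak and to
single-bin noise spikes; with the synthetic defaults the recovered lead is
within ~1 s of the programmed value, the residual reflecting the onset
advance of the symmetric smoothing filter.

## Synthetic generators: the stated world

All generators are pure functions of (config, seed). Defaults encode the
conditions the analysis assumes: 2 s frames, 400 s recordings, 12 μm
junctions, 0.1 μm pixels, 1 μm cluster scale, 20 s cluster-size lead.

**Tracks.** Active-vertex motion is a velocity-OU persistent walk
(persistence 30 s, speed sd 0.01 μm/s) plus 0.01 μm/s drift → MSD exponent
between 1 and 2 (2 in the zero-noise limit). Passive-vertex motion is
position-OU confinement (rate 0.5 s⁻¹, diffusivity 0.011 μm²/s →
stationary spread 0.15 μm) around a cage center that hops 0.5 μm at rate
0.005 s⁻¹; as the confinement rate → 0 at fixed diffusivity the motion
becomes Brownian.

**Junction recordings.** `gen_shortening_event` embeds the two-vertex
model along x with its transverse OU coordinates as y. Asymmetric = model
defaults (shortening, active/passive structure); symmetric = equal small
k/γ = 10⁻² s⁻¹ with the piston disengaged (non-shortening, large length
fluctuations).

**Intensity profiles.** Clusters are rendered as boxcar occupancy domains
— mean width = cluster scale, width dispersion 25%, brightness dispersion
30% — at quasi-regular spacing (5× the scale, 10% jitter), convolved with
a 0.1 μm PSF, plus additive noise (sd 0.1 of unit cluster amplitude).
Sharp-edged domains are deliberate: any smooth (e.g. Gaussian) bump profile
has a band-limited correlation that is quadratic at r = 0 and cannot decay
near-exponentially, whereas sharp edges give the triangular, near-linear
decay that characterizes ordered cluster fields. The spacing ratio was
calibrated by simulation, before any acceptance test existed, so that the
ensemble zero-crossing readout matches the stated cluster scale as closely
as the finite junction allows; the readout converges to ≈ 0.87× the scale
(the residual inward pull comes from the mean-subtraction baseline of the
duty cycle and the few clusters per 12 μm junction) and saturates there —
this known ~13% bias is inherent to the r₀ readout on short junctions, not
tunable away. The diffuse regime renders an envelope much broader than the
junction plus the same noise. Cluster geometry is drawn independently per
frame; real clusters persist between frames, so temporal correlations of
the readout noise are *not* emulated.

**Coupled series.** Junction length is a staircase of three raised-cosine
drops (2.2 μm over 30 s, onsets drawn in [80, 130], [200, 250],
[320, 370] s — several pulses per 400 s trace, as in pulsatile shortening
data) plus 0.1 μm measurement noise. The cluster scale gains Gaussian
pulses (amplitude 0.4 μm, sd 8 s) centered exactly `lead_time` before each
onset, and frames are rendered from that scale series with the whole
cluster geometry scaled proportionally (self-similar growth), so the
autocorrelation readout responds linearly — lead recovery is a true
end-to-end test of pulse detection + per-frame sizing + event-triggered
averaging, not circular smoothing.

**What a green test establishes.** That the estimators recover the
statistical structure they were designed for, at realistic noise levels,
from data whose generative process is known. The generators do not emulate
segmentation/tracking errors, photobleaching, PSF anisotropy, temporal
persistence of cluster geometry, or 3D motion; agreement on synthetic data
does not validate the upstream imaging pipeline.

## Known limitations

- The r₀ cluster-size readout on 12 μm junctions carries the ~13% inward
  bias described above; comparative statements (active vs passive, ordered
  vs diffuse, leads) are unaffected.
- Pulse-onset detection with a symmetric smoothing kernel is advanced by
  up to ~half the kernel support at low thresholds; the lead estimator
  absorbs most but not all of it (residual ≲ 1 s at defaults).
- χ₄ magnitudes depend on the declared normalization and on the overlap
  cutoff; only comparisons under a fixed convention are meaningful.
- The model's force units are arbitrary; only k/γ (s⁻¹) is physically
  interpreted, and no calibration to absolute forces is attempted.
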