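"""Stochastic two-vertex viscoelastic model of junction shortening.

The junction is reduced to two vertices at positions x_L < x_R on a line.
Each vertex is pulled by a spring of stiffness k toward a *dynamic rest
position* driven by a piston that contracts the rest length from L0 to
(1−c)·L0 over a time t_p following a power law with exponent ψ, and is
damped by a friction γ (overdamped dynamics — no inertia). An
Ornstein–Uhlenbeck colored noise term perturbs each vertex's velocity:

    dx_L/dt = (k_L/γ_L) (rest_L(t) − x_L) + ζ_L(t)
    dx_R/dt = (k_R/γ_R) (rest_R(t) − x_R) + ζ_R(t)

    rest_L(t) = x_L(0) + (c L0 / 2) min(t/t_p, 1)^ψ_L   (mirrored for R)

The *viscoelastic parameter* k/γ (s⁻¹) is the inverse relaxation time of a
vertex toward its rest position; mechanical heterogeneity along the junction
is encoded as asymmetry in k/γ (and ψ) between the two vertices. Optional
transverse coordinates follow an OU process with per-vertex rate k_T,
modelling the transverse confinement that differs between active and
passive vertices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .relaxation_analysis import moving_average


@dataclass(frozen=True)
class ModelParams:
    """Two-vertex model configuration (arbitrary force units; lengths μm, times s).

    Defaults are the asymmetric "effective shortening" regime: a stiff/fast
    left (active-side) vertex with k/γ = 1 s⁻¹ against a compliant/slow right
    vertex with k/γ = 10⁻² s⁻¹, both driven by a c = 0.8 piston over
    t_p = 300 s with rest-length exponent ψ = 1.5.
    """

    L0: float = 10.0
    k_L: float = 1.0
    k_R: float = 0.1
    gamma_L: float = 1.0
    gamma_R: float = 10.0
    psi_L: float = 1.5
    psi_R: float = 1.5
    contraction_fraction: float = 0.8
    piston_time: float = 300.0
    noise_sd: float = 0.01       # μm/s, OU velocity-noise amplitude
    noise_corr_time: float = 10.0
    dt: float = 0.1
    T_max: float = 400.0
    k_T_L: float = 0.2           # s⁻¹, transverse OU relaxation rates
    k_T_R: float = 0.05
    x0_offset_L: float = 0.0     # μm, initial displacement from the rest position
    x0_offset_R: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("L0", "k_L", "k_R", "gamma_L", "gamma_R", "psi_L", "psi_R",
                     "piston_time", "noise_corr_time", "dt", "T_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.contraction_fraction <= 1):
            # c = 0 means the piston is disengaged (non-shortening junction)
            raise ValueError("contraction_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def kg_L(self) -> float:
        """Viscoelastic parameter k_L/γ_L (s⁻¹)."""
        return self.k_L / self.gamma_L

    @property
    def kg_R(self) -> float:
        return self.k_R / self.gamma_R

    def check_stability(self) -> None:
        """Explicit Euler–Maruyama stability: dt must resolve the fastest timescale."""
        fastest = min(1.0 / self.kg_L, 1.0 / self.kg_R, self.noise_corr_time,
                      1.0 / max(self.k_T_L, self.k_T_R, 1e-12))
        if self.dt > fastest / 5:
            raise ValueError(
                f"dt={self.dt} too large for fastest timescale {fastest:.3g} s "
                "(require dt <= timescale/5)"
            )


@dataclass(frozen=True)
class SimulationResult:
    times: np.ndarray
    x_L: np.ndarray
    x_R: np.ndarray
    rest_L: np.ndarray
    rest_R: np.ndarray
    zeta_L: np.ndarray
    zeta_R: np.ndarray
    y_L: np.ndarray
    y_R: np.ndarray
    params: ModelParams
    success: bool = field(default=False)

    @property
    def length(self) -> np.ndarray:
        """Junction length L(t) = x_R − x_L (clamped non-negative by the integrator)."""
        return self.x_R - self.x_L

    @property
    def force_L(self) -> np.ndarray:
        return self.params.k_L * (self.rest_L - self.x_L)

    @property
    def force_R(self) -> np.ndarray:
        return self.params.k_R * (self.rest_R - self.x_R)


def colored_noise(
    tau_c: float, sigma: float, dt: float, n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck noise sequence of length n.

    ζ_{i+1} = ζ_i (1 − dt/τ_c) + σ sqrt(2 dt/τ_c) g_i with ζ_0 drawn from the
    stationary distribution; stationary variance σ² and autocorrelation
    exp(−τ/τ_c). Identical seeds give identical series.
    """
    if tau_c <= 0 or dt <= 0:
        raise ValueError("tau_c and dt must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if dt >= tau_c:
        raise ValueError("dt must be smaller than tau_c for a stable OU update")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma == 0:
        return np.zeros(n)
    z0 = rng.normal(0.0, sigma)
    a = 1.0 - dt / tau_c
    b = sigma * np.sqrt(2.0 * dt / tau_c)
    g = rng.standard_normal(n - 1)
    # z[i+1] = a z[i] + b g[i] as an IIR filter with initial condition z0
    tail, _ = lfilter([b], [1.0, -a], g, zi=np.array([a * z0]))
    return np.concatenate([[z0], tail])


def rest_positions(params: ModelParams, t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Piston-driven rest positions; rest length shrinks monotonically to (1−c)·L0.

    The initial vertex positions are taken as x_L(0) = 0, x_R(0) = L0.
    """
    t = np.asarray(t, dtype=float)
    frac = np.minimum(np.maximum(t, 0.0) / params.piston_time, 1.0)
    half = params.contraction_fraction * params.L0 / 2.0
    rest_L = 0.0 + half * frac**params.psi_L
    rest_R = params.L0 - half * frac**params.psi_R
    return rest_L, rest_R


def simulate_junction(params: ModelParams, transverse: bool = True) -> SimulationResult:
    """Integrate the two-vertex equations of motion (Euler–Maruyama).

    Deterministic given ``params.seed``. If a step would produce x_R < x_L
    the vertices are clamped to their midpoint (L = 0 reflecting barrier;
    a junction cannot have negative length).
    """
    params.check_stability()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.T_max / params.dt)) + 1
    t = params.dt * np.arange(n)
    rest_L, rest_R = rest_positions(params, t)
    zeta_L = colored_noise(params.noise_corr_time, params.noise_sd, params.dt, n, rng)
    zeta_R = colored_noise(params.noise_corr_time, params.noise_sd, params.dt, n, rng)
    if transverse:
        eta_L = colored_noise(params.noise_corr_time, params.noise_sd, params.dt, n, rng)
        eta_R = colored_noise(params.noise_corr_time, params.noise_sd, params.dt, n, rng)
    x_L = np.empty(n)
    x_R = np.empty(n)
    y_L = np.zeros(n)
    y_R = np.zeros(n)
    x_L[0], x_R[0] = params.x0_offset_L, params.L0 + params.x0_offset_R
    kg_L, kg_R = params.kg_L, params.kg_R
    dt = params.dt
    for i in range(n - 1):
        x_L[i + 1] = x_L[i] + dt * (kg_L * (rest_L[i] - x_L[i]) + zeta_L[i])
        x_R[i + 1] = x_R[i] + dt * (kg_R * (rest_R[i] - x_R[i]) + zeta_R[i])
        if x_R[i + 1] < x_L[i + 1]:
            mid = 0.5 * (x_L[i + 1] + x_R[i + 1])
            x_L[i + 1] = mid
            x_R[i + 1] = mid
        if transverse:
            y_L[i + 1] = y_L[i] + dt * (-params.k_T_L * y_L[i] + eta_L[i])
            y_R[i + 1] = y_R[i] + dt * (-params.k_T_R * y_R[i] + eta_R[i])
    result = SimulationResult(t, x_L, x_R, rest_L, rest_R, zeta_L, zeta_R,
                              y_L, y_R, params)
    return replace(result, success=shortening_success(result))


def shortening_success(
    result: SimulationResult,
    f_s: float = 0.33,
    hold: float = 10.0,
    smoothing_window: float = 10.0,
) -> bool:
    """True iff the smoothed length stays below f_s·L0 for at least ``hold`` seconds.

    The hold requirement rejects noise-driven grazing of the threshold: a T1
    exchange needs sustained near-zero length, not a transient dip.
    """
    L = moving_average(result.length, smoothing_window, result.params.dt)
    below = L <= f_s * result.params.L0
    dt = result.params.dt
    needed = int(np.ceil(hold / dt))
    run = 0
    for flag in below:
        run = run + 1 if flag else 0
        if run >= needed:
            return True
    return False


def parameter_sweep(
    kg_L_values: Sequence[float] | None = None,
    kg_R_values: Sequence[float] | None = None,
    psi_values: Sequence[float] | None = None,
    n_reps: int = 10,
    base: ModelParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Success probability over a grid of viscoelastic parameters and ψ.

    For each (k/γ_L, k/γ_R, ψ) cell, ``n_reps`` seeds are simulated and the
    fraction of successful shortenings recorded. ψ is applied to both
    vertices. Defaults: k/γ on 8 log-spaced points over [10⁻³, 1] s⁻¹ and ψ
    on 7 points over [0.5, 2.0]. Returns a long table with columns
    ``kg_L, kg_R, psi, success_prob, n_reps``.
    """
    if kg_L_values is None:
        kg_L_values = np.logspace(-3, 0, 8)
    if kg_R_values is None:
        kg_R_values = np.logspace(-3, 0, 8)
    if psi_values is None:
        psi_values = np.linspace(0.5, 2.0, 7)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = base or ModelParams()
    rows = []
    for kg_L, kg_R, psi in itertools.product(kg_L_values, kg_R_values, psi_values):
        wins = 0
        for rep in range(n_reps):
            params = replace(
                base,
                k_L=kg_L * base.gamma_L,
                k_R=kg_R * base.gamma_R,
                psi_L=psi,
                psi_R=psi,
                seed=seed + hash((round(np.log10(kg_L), 6), round(np.log10(kg_R), 6),
                                  round(psi, 6), rep)) % (2**31),
            )
            wins += simulate_junction(params, transverse=False).success
        rows.append((kg_L, kg_R, psi, wins / n_reps, n_reps))
    return pd.DataFrame(rows, columns=["kg_L", "kg_R", "psi", "success_prob", "n_reps"])


def sweep_heatmap(table: pd.DataFrame, path: str, kg_R: float | None = None):
    """Render a success-probability heatmap (k/γ_L vs ψ) for one k/γ_R slice."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if kg_R is None:
        kg_R = sorted(table["kg_R"].unique())[0]
    sel = table[np.isclose(table["kg_R"], kg_R)]
    pivot = sel.pivot_table(index="kg_L", columns="psi", values="success_prob")
    fig, ax = plt.subplots(figsize=(6, 4))
    x_lo, x_hi = pivot.columns.min(), pivot.columns.max()
    if x_hi <= x_lo:
        x_hi = x_lo + 1.0
    im = ax.imshow(
        pivot.to_numpy(), origin="lower", aspect="auto", vmin=0, vmax=1,
        extent=[x_lo, x_hi, 0, len(pivot.index)],
        cmap="viridis",
    )
    ax.set_yticks(np.arange(len(pivot.index)) + 0.5)
    ax.set_yticklabels([f"{v:.3g}" for v in pivot.index])
    ax.set_xlabel("rest-length exponent ψ")
    ax.set_ylabel("viscoelastic parameter k/γ (left vertex, s⁻¹)")
    ax.set_title(f"P(successful shortening), k/γ right = {kg_R:.3g} s⁻¹")
    fig.colorbar(im, ax=ax, label="success probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
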