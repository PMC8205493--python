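"""In-line/transverse decomposition of vertex motion and local-stiffness proxies.

A vertex bounding a shortening junction moves mostly along the junction axis;
how much it wanders *perpendicular* to that axis reports on the local
mechanical environment. The transverse hop function R_T — a two-half-window
fluctuation measure in the style of cage-hop detectors — is inversely related
to the local stiffness: stiff surroundings suppress transverse excursions.
The straightness index S complements it as a global directionality measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .tracks_io import JunctionRecording, ValidationError, VertexTrack

#: Default hop-function window (s): 10 frames at the nominal 2 s interval.
DEFAULT_WINDOW_W = 20.0


class AxisConvention(str, Enum):
    INITIAL_AXIS = "initial_axis"
    INSTANTANEOUS_AXIS = "instantaneous_axis"


class HopMethod(str, Enum):
    HOP = "hop"                 # two-half-window Candelier-style form
    WINDOWED_SD = "windowed_sd"  # plain moving standard deviation


@dataclass(frozen=True)
class DecomposedTrack:
    """A vertex track in junction-axis coordinates, relative to its start point."""

    vertex_id: str
    times: np.ndarray
    inline: np.ndarray       # μm, along the junction axis
    transverse: np.ndarray   # μm, perpendicular
    axis_convention: AxisConvention


@dataclass(frozen=True)
class TransverseStats:
    times: np.ndarray        # centers of valid windows (s)
    RT_series: np.ndarray    # μm
    mean_RT: float           # μm
    window_W: float          # s
    method: HopMethod


@dataclass(frozen=True)
class StraightnessResult:
    S: float                 # in [0, 1]
    defined: bool = True


def decompose_track(
    rec: JunctionRecording,
    vertex_id: str,
    convention: AxisConvention | str = AxisConvention.INITIAL_AXIS,
) -> DecomposedTrack:
    """Project a vertex's motion onto in-line and transverse junction axes.

    ``initial_axis`` (default): the axis is the fixed unit vector from this
    vertex's initial position toward the other vertex's initial position;
    displacements from the initial position are projected onto it and its
    +90° rotation. ``instantaneous_axis`` recomputes the axis per frame from
    the current vertex pair.
    """
    convention = AxisConvention(convention)
    if rec.vertex_a.vertex_id == vertex_id:
        this, other = rec.vertex_a, rec.vertex_b
    elif rec.vertex_b.vertex_id == vertex_id:
        this, other = rec.vertex_b, rec.vertex_a
    else:
        raise ValueError(f"vertex {vertex_id!r} not in junction {rec.junction_id!r}")
    disp = this.positions - this.positions[0]
    if convention is AxisConvention.INITIAL_AXIS:
        axis = other.positions[0] - this.positions[0]
        norm = np.linalg.norm(axis)
        if norm <= 0:
            raise ValidationError("coincident initial vertices: axis undefined")
        u = axis / norm
        n_hat = np.array([-u[1], u[0]])
        inline = disp @ u
        transverse = disp @ n_hat
    else:
        axes = other.positions - this.positions
        norms = np.linalg.norm(axes, axis=1)
        if np.any(norms <= 0):
            raise ValidationError("coincident vertices: instantaneous axis undefined")
        u = axes / norms[:, None]
        n_hat = np.column_stack([-u[:, 1], u[:, 0]])
        inline = np.sum(disp * u, axis=1)
        transverse = np.sum(disp * n_hat, axis=1)
    return DecomposedTrack(vertex_id, this.times.copy(), inline, transverse, convention)


def transverse_hop(
    dec: DecomposedTrack,
    window_W: float = DEFAULT_WINDOW_W,
    method: HopMethod | str = HopMethod.HOP,
) -> TransverseStats:
    """Transverse hop function R_T(t) over a sliding window of width W.

    For each center t with a full window, the window [t−W/2, t+W/2] is split
    into halves H1 and H2 and

        R_T(t) = [ <(y − <y>_H2)²>_H1 · <(y − <y>_H1)²>_H2 ] ^ (1/4),

    where y is the transverse coordinate: each half's spread is measured
    about the *other* half's mean, so both diffusive wandering within the
    window and discrete hops between the halves raise R_T.
    ``windowed_sd`` replaces this with the plain standard deviation of y in
    the window.
    """
    method = HopMethod(method)
    t = dec.times
    dt = float(np.median(np.diff(t)))
    if np.any(np.abs(np.diff(t) - dt) > 1e-6 * dt):
        raise ValidationError("transverse_hop requires uniform sampling")
    span = t[-1] - t[0]
    if span < 2 * window_W:
        raise ValidationError("track span must be at least twice the window")
    half = max(1, int(round(window_W / (2 * dt))))
    y = dec.transverse
    centers, rt = [], []
    for i in range(half, t.size - half):
        h1 = y[i - half : i]
        h2 = y[i : i + half]
        if method is HopMethod.HOP:
            v12 = np.mean((h1 - h2.mean()) ** 2)
            v21 = np.mean((h2 - h1.mean()) ** 2)
            rt.append((v12 * v21) ** 0.25)
        else:
            w = y[i - half : i + half]
            rt.append(np.std(w))
        centers.append(t[i])
    rt_arr = np.asarray(rt)
    return TransverseStats(
        np.asarray(centers), rt_arr, float(rt_arr.mean()), float(window_W), method
    )


def straightness_index(track: VertexTrack) -> StraightnessResult:
    """S = net displacement / path length; 1 for perfectly directed motion."""
    if track.n_frames < 3:
        raise ValidationError("straightness index needs >= 3 frames")
    path = track.path_length()
    if path <= 0:
        return StraightnessResult(float("nan"), defined=False)
    return StraightnessResult(min(1.0, track.net_displacement() / path))
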