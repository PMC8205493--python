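"""Domain types and I/O for tricellular-vertex tracks and junction intensity profiles.

The objects here are the common currency of the package: time-stamped 2D
vertex trajectories (:class:`VertexTrack`), paired-vertex junction recordings
with a derived length series (:class:`JunctionRecording`), and per-frame
intensity-vs-arc-length profiles along a junction line of interest
(:class:`IntensityProfileSeries`).

Units are seconds and micrometers throughout. Track tables are long-format
delimited text with columns ``junction_id, vertex_id, time_s, x_um, y_um``;
intensity profiles are dense matrices (rows = frames, columns = arc
positions) with a sidecar table of per-frame vertex arc positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("junctionmech")

#: Nominal acquisition interval (s) of the time-lapse data this package targets.
DEFAULT_FRAME_INTERVAL = 2.0

#: Default arc-length sampling (μm/pixel) of intensity profiles.
DEFAULT_PIXEL_SIZE = 0.1

TRACK_COLUMNS = ("junction_id", "vertex_id", "time_s", "x_um", "y_um")


class FormatError(ValueError):
    """A file does not have the expected columns or layout."""


class ValidationError(ValueError):
    """Data violate a domain-type invariant."""


class ShorteningClass(str, Enum):
    SHORTENING = "shortening"
    NON_SHORTENING = "non_shortening"
    UNCLASSIFIED = "unclassified"


class ReferenceFrame(str, Enum):
    FIXED = "fixed"
    LANDMARK = "landmark"
    MIDPOINT = "midpoint"


def _as_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValidationError("times must be a 1D sequence of length >= 2")
    if not np.all(np.isfinite(t)):
        raise ValidationError("times contain non-finite values")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    return t


@dataclass(frozen=True)
class VertexTrack:
    """One tricellular vertex: positions r(t) in μm at timestamps in s."""

    vertex_id: str
    times: np.ndarray
    positions: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self):
        t = _as_times(self.times)
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValidationError("positions must have shape (n, 2)")
        if p.shape[0] != t.size:
            raise ValidationError("times and positions must have equal length")
        if not np.all(np.isfinite(p)):
            raise ValidationError("positions contain non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        """Median sampling interval (s)."""
        return float(np.median(np.diff(self.times)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.times)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))

    def net_displacement(self) -> float:
        """Straight-line start-to-end displacement magnitude (μm)."""
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    def path_length(self) -> float:
        """Total traversed path length (μm)."""
        steps = np.diff(self.positions, axis=0)
        return float(np.sum(np.linalg.norm(steps, axis=1)))


class LandmarkTrack(VertexTrack):
    """A slowly moving tissue landmark used to define a relative reference frame."""


def junction_length_series(a: VertexTrack, b: VertexTrack) -> np.ndarray:
    """Per-frame Euclidean distance L(t) (μm) between two vertices on a shared time base."""
    if a.times.size != b.times.size or not np.allclose(a.times, b.times):
        raise ValidationError("vertex tracks do not share a time base")
    return np.linalg.norm(b.positions - a.positions, axis=1)


@dataclass(frozen=True)
class JunctionRecording:
    """A v-junction: two paired vertex tracks and the junction length L(t)."""

    junction_id: str
    vertex_a: VertexTrack
    vertex_b: VertexTrack
    length_series: np.ndarray = field(default=None)  # type: ignore[assignment]
    shortening_class: ShorteningClass = ShorteningClass.UNCLASSIFIED
    condition_label: str = "control"

    def __post_init__(self):
        L = junction_length_series(self.vertex_a, self.vertex_b)
        if self.length_series is not None:
            given = np.asarray(self.length_series, dtype=float)
            if given.shape != L.shape or not np.allclose(given, L, atol=1e-9):
                raise ValidationError(
                    f"junction {self.junction_id}: length_series inconsistent "
                    "with vertex positions"
                )
        object.__setattr__(self, "length_series", L)
        if L[0] <= 0:
            raise ValidationError(
                f"junction {self.junction_id}: initial length must be positive"
            )

    @property
    def initial_length(self) -> float:
        return float(self.length_series[0])

    @property
    def times(self) -> np.ndarray:
        return self.vertex_a.times

    @property
    def frame_interval(self) -> float:
        return self.vertex_a.frame_interval


@dataclass(frozen=True)
class IntensityProfileSeries:
    """Per-frame intensity I(x, t) along a junction line of interest.

    ``arc_positions`` are uniformly spaced arc-length samples (μm);
    ``vertex_positions`` holds the per-frame arc coordinates of the two
    bounding vertices, shape (n_frames, 2).
    """

    junction_id: str
    times: np.ndarray
    arc_positions: np.ndarray
    profiles: np.ndarray
    vertex_positions: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.arc_positions, dtype=float)
        I = np.asarray(self.profiles, dtype=float)
        v = np.asarray(self.vertex_positions, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValidationError("arc_positions must be 1D with >= 2 samples")
        dx = np.diff(x)
        if np.any(np.abs(dx - dx[0]) > 1e-9):
            raise ValidationError("arc_positions must be uniformly spaced")
        if I.ndim != 2 or I.shape != (t.size, x.size):
            raise ValidationError("profiles must have shape (n_frames, n_arc)")
        if v.shape != (t.size, 2):
            raise ValidationError("vertex_positions must have shape (n_frames, 2)")
        if np.any(v < x.min() - 1e-9) or np.any(v > x.max() + 1e-9):
            raise ValidationError("vertex_positions must lie within the arc range")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "arc_positions", x)
        object.__setattr__(self, "profiles", I)
        object.__setattr__(self, "vertex_positions", v)
        object.__setattr__(self, "pixel_size", float(dx[0]))

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path, dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect == "auto":
        return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_vertex_tracks(
    path: str | Path,
    dialect: str = "auto",
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> list[JunctionRecording]:
    """Read a long-format track table into one :class:`JunctionRecording` per junction.

    The table must contain columns ``junction_id, vertex_id, time_s, x_um,
    y_um``; each junction must have exactly two vertex ids sampled on a
    shared, strictly increasing time base.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    recordings = []
    for junction_id, jdf in df.groupby("junction_id", sort=True):
        vertex_ids = sorted(jdf["vertex_id"].unique())
        if len(vertex_ids) != 2:
            raise ValidationError(
                f"junction {junction_id!r} has {len(vertex_ids)} vertex ids "
                f"({vertex_ids}); exactly 2 required"
            )
        tracks = []
        for vid in vertex_ids:
            vdf = jdf[jdf["vertex_id"] == vid].sort_values("time_s")
            tracks.append(
                VertexTrack(
                    vertex_id=str(vid),
                    times=vdf["time_s"].to_numpy(),
                    positions=vdf[["x_um", "y_um"]].to_numpy(),
                    frame_interval=frame_interval,
                )
            )
        recordings.append(
            JunctionRecording(
                junction_id=str(junction_id), vertex_a=tracks[0], vertex_b=tracks[1]
            )
        )
    return recordings


def write_vertex_tracks(
    recordings: Iterable[JunctionRecording], path: str | Path, dialect: str = "auto"
) -> None:
    """Write recordings as a long-format track table (inverse of :func:`read_vertex_tracks`)."""
    path = Path(path)
    rows = []
    for rec in recordings:
        for track in (rec.vertex_a, rec.vertex_b):
            for t, (x, y) in zip(track.times, track.positions):
                rows.append((rec.junction_id, track.vertex_id, t, x, y))
    pd.DataFrame(rows, columns=list(TRACK_COLUMNS)).to_csv(
        path, sep=_sep_for(path, dialect), index=False, float_format="%.12g"
    )


def read_intensity_profiles(
    matrix_path: str | Path,
    vertices_path: str | Path,
    junction_id: str = "junction",
    dialect: str = "auto",
) -> IntensityProfileSeries:
    """Read a dense profile matrix (header row = arc positions, first column
    ``time_s``) plus a sidecar vertex-position table (``time_s, vertex_a_um,
    vertex_b_um``)."""
    matrix_path = Path(matrix_path)
    mdf = pd.read_csv(matrix_path, sep=_sep_for(matrix_path, dialect))
    if mdf.columns[0] != "time_s":
        raise FormatError(f"{matrix_path}: first column must be 'time_s'")
    arc = np.array([float(c) for c in mdf.columns[1:]])
    vertices_path = Path(vertices_path)
    vdf = pd.read_csv(vertices_path, sep=_sep_for(vertices_path, dialect))
    for col in ("time_s", "vertex_a_um", "vertex_b_um"):
        if col not in vdf.columns:
            raise FormatError(f"{vertices_path}: missing column {col!r}")
    vdf = vdf.sort_values("time_s")
    times = mdf["time_s"].to_numpy(dtype=float)
    if not np.allclose(times, vdf["time_s"].to_numpy(dtype=float)):
        raise ValidationError("profile matrix and vertex table time bases differ")
    return IntensityProfileSeries(
        junction_id=junction_id,
        times=times,
        arc_positions=arc,
        profiles=mdf.iloc[:, 1:].to_numpy(dtype=float),
        vertex_positions=vdf[["vertex_a_um", "vertex_b_um"]].to_numpy(dtype=float),
    )


def write_intensity_profiles(
    series: IntensityProfileSeries,
    matrix_path: str | Path,
    vertices_path: str | Path,
    dialect: str = "auto",
) -> None:
    matrix_path = Path(matrix_path)
    cols = ["time_s"] + [f"{x:.6g}" for x in series.arc_positions]
    data = np.column_stack([series.times, series.profiles])
    pd.DataFrame(data, columns=cols).to_csv(
        matrix_path, sep=_sep_for(matrix_path, dialect), index=False,
        float_format="%.12g",
    )
    vertices_path = Path(vertices_path)
    pd.DataFrame(
        {
            "time_s": series.times,
            "vertex_a_um": series.vertex_positions[:, 0],
            "vertex_b_um": series.vertex_positions[:, 1],
        }
    ).to_csv(vertices_path, sep=_sep_for(vertices_path, dialect), index=False,
             float_format="%.12g")


def write_run_summary(summary: dict, path: str | Path) -> None:
    """Write a JSON run summary (parameters, seeds, headline numbers)."""
    Path(path).write_text(json.dumps(summary, indent=2, default=float) + "\n")


# ---------------------------------------------------------------------------
# Reference-frame transforms and resampling
# ---------------------------------------------------------------------------

def _shift_track(track: VertexTrack, shift: np.ndarray) -> VertexTrack:
    return replace(track, positions=track.positions - shift)


def to_reference_frame(
    rec: JunctionRecording,
    mode: ReferenceFrame | str = ReferenceFrame.FIXED,
    landmark: LandmarkTrack | None = None,
) -> JunctionRecording:
    """Express a recording in a fixed, landmark-relative, or midpoint-relative frame.

    All modes are per-frame translations, so the junction length series is
    invariant. Landmark positions are linearly interpolated onto the
    recording's time base and must cover it (no extrapolation).
    """
    mode = ReferenceFrame(mode)
    if mode is ReferenceFrame.FIXED:
        return rec
    if mode is ReferenceFrame.LANDMARK:
        if landmark is None:
            raise ValueError("landmark mode requires a LandmarkTrack")
        t = rec.times
        if t[0] < landmark.times[0] - 1e-9 or t[-1] > landmark.times[-1] + 1e-9:
            raise ValidationError("landmark track does not cover the recording times")
        shift = np.column_stack(
            [np.interp(t, landmark.times, landmark.positions[:, k]) for k in (0, 1)]
        )
    else:  # midpoint
        shift = 0.5 * (rec.vertex_a.positions + rec.vertex_b.positions)
    return replace(
        rec,
        vertex_a=_shift_track(rec.vertex_a, shift),
        vertex_b=_shift_track(rec.vertex_b, shift),
        length_series=None,
    )


def resample_uniform(track: VertexTrack, dt: float) -> VertexTrack:
    """Linearly interpolate a track onto a uniform grid from first to last timestamp."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = track.times[-1] - track.times[0]
    if span < 2 * dt:
        raise ValidationError("track must span at least 2*dt")
    n = int(np.floor(span / dt)) + 1
    t = track.times[0] + dt * np.arange(n)
    pos = np.column_stack(
        [np.interp(t, track.times, track.positions[:, k]) for k in (0, 1)]
    )
    return replace(track, times=t, positions=pos, frame_interval=dt)
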