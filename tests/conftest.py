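import numpy as np
import pytest

from junctionmech import JunctionRecording, VertexTrack


def make_track(positions, dt=2.0, vertex_id="v", t0=0.0):
    positions = np.asarray(positions, dtype=float)
    times = t0 + dt * np.arange(len(positions))
    return VertexTrack(vertex_id, times, positions, frame_interval=dt)


def make_recording(pos_a, pos_b, dt=2.0, junction_id="j"):
    return JunctionRecording(
        junction_id=junction_id,
        vertex_a=make_track(pos_a, dt, "a"),
        vertex_b=make_track(pos_b, dt, "b"),
    )


def brownian_track(rng, n, D=0.01, dt=2.0, vertex_id="bm"):
    steps = rng.normal(0.0, np.sqrt(2 * D * dt), (n - 1, 2))
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return make_track(pos, dt, vertex_id)


def ou_track_1d(rng, n, k, sigma_stat, dt=2.0):
    """Stationary 1D OU series with relaxation rate k and stationary sd sigma_stat."""
    decay = np.exp(-k * dt)
    kick = sigma_stat * np.sqrt(1 - decay**2)
    y = np.empty(n)
    y[0] = rng.normal(0.0, sigma_stat)
    for i in range(n - 1):
        y[i + 1] = y[i] * decay + rng.normal(0.0, kick)
    return y


def ou_track_2d(rng, n, k, sigma_stat, dt=2.0, vertex_id="ou"):
    pos = np.column_stack(
        [ou_track_1d(rng, n, k, sigma_stat, dt), ou_track_1d(rng, n, k, sigma_stat, dt)]
    )
    return make_track(pos, dt, vertex_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
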