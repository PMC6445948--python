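import numpy as np
import pytest

from phasevel import Track, VelocitySeries
from phasevel.simulate import _integrate_positions


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def make_piecewise_series(speeds, lengths, noise_sd=0.0, rng=None,
                          **series_kw) -> tuple[VelocitySeries, np.ndarray]:
    """Piecewise-constant speed signal plus optional white noise.

    Returns (series, true_values)."""
    true = np.concatenate([np.full(l, s) for s, l in zip(speeds, lengths)])
    v = true.copy()
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, len(v))
    return VelocitySeries(v, **series_kw), true


def make_piecewise_track(speeds, lengths, pos_noise_sd=0.0, rng=None,
                         heading_jitter=0.05, track_id="t") -> tuple[Track, np.ndarray]:
    """A 2D track whose tip moves at a piecewise-constant speed.

    Returns (track, true_speed_per_interval)."""
    rng = rng or np.random.default_rng(0)
    speed = np.concatenate([np.full(l, s) for s, l in zip(speeds, lengths)])
    pos = _integrate_positions(rng, speed, heading_jitter)
    if pos_noise_sd > 0:
        pos = pos + rng.normal(0.0, pos_noise_sd, pos.shape)
    return Track(track_id, np.arange(len(pos)), pos[:, 0], pos[:, 1]), speed


def constant_velocity_track(vx=3.0, vy=4.0, n=100, track_id="cv") -> Track:
    f = np.arange(n)
    return Track(track_id, f, vx * f, vy * f)
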