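"""Synthetic motility data with ground truth.

Two generators make every pipeline stage testable without microscope
data:

* :func:`simulate_tracks` draws 2D tip trajectories with known speed
  profiles (constant or sinusoidally modulated), slowly wandering
  heading, Gaussian positional noise and sparse large impulses that
  mimic tracking blunders.  This is the input of the filter benchmark.
* :func:`simulate_image_sequence` renders a fluorescence-like movie of
  elliptical filaments gliding over a uniform background, each changing
  speed twice, with additive Gaussian intensity noise — plus the exact
  tip tracks and speeds used to render it.

All randomness flows from a single seed through numpy SeedSequence
spawning, so each filament has an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .filters import VelocitySeries
from .tracks import Track, write_tracks_csv

__all__ = [
    "TrackSimConfig",
    "ImageSimConfig",
    "GroundTruth",
    "simulate_tracks",
    "simulate_image_sequence",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class TrackSimConfig:
    """Conditions of the simulated velocity-track benchmark.

    Defaults describe tracks resembling real filament velocity data:
    base speeds of 2-8 px/frame, half the tracks with a sinusoidal speed
    modulation (periods of 1-3 s at 10 fps), positional noise of 1 px SD
    and 8% impulsive outliers of 5 px SD standing in for gross tracking
    errors.
    """

    n_tracks: int = 330
    n_frames: int = 100
    profile: str = "mixed"  # constant | periodic | mixed (50/50)
    base_speed_range: tuple[float, float] = (2.0, 8.0)
    periodic_amplitude_frac: float = 0.3
    periodic_period_frames: tuple[float, float] = (10.0, 30.0)
    heading_jitter_sd: float = 0.05  # rad/frame
    gaussian_pos_noise_sd: float = 1.0  # px
    impulse_prob: float = 0.08
    impulse_sd: float = 5.0  # px
    seed: int = 42

    def __post_init__(self) -> None:
        if self.profile not in ("constant", "periodic", "mixed"):
            raise ConfigError(f"unknown profile {self.profile!r}")
        if not 0 <= self.impulse_prob <= 1:
            raise ConfigError("impulse_prob must be in [0, 1]")
        if min(self.gaussian_pos_noise_sd, self.impulse_sd,
               self.heading_jitter_sd) < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.base_speed_range[0] <= 0:
            raise ConfigError("base speeds must be positive")
        if self.n_frames < 2 or self.n_tracks < 1:
            raise ConfigError("need n_frames >= 2 and n_tracks >= 1")


@dataclass
class ImageSimConfig:
    """Conditions of the simulated IVMA image sequence: 100 frames of
    8-bit 700x700 px, background 80, 30 elliptical filaments at
    intensity 130 (sizes 17x3 and 8x3 px), speeds 2-8 px/frame with two
    speed changes per filament, Gaussian intensity noise SD 15."""

    n_frames: int = 100
    width: int = 700
    height: int = 700
    bit_depth: int = 8
    background_intensity: float = 80.0
    filament_intensity: float = 130.0
    n_filaments: int = 30
    filament_sizes: tuple[tuple[float, float], ...] = ((17.0, 3.0), (8.0, 3.0))
    speed_range: tuple[float, float] = (2.0, 8.0)
    n_speed_changes: int = 2
    min_epoch_intervals: int = 10
    intensity_noise_sd: float = 15.0  # grey levels
    heading_jitter_sd: float = 0.08  # rad/frame
    seed: int = 42

    def __post_init__(self) -> None:
        n_int = self.n_frames - 1
        if n_int < (self.n_speed_changes + 1) * self.min_epoch_intervals:
            raise ConfigError(
                f"{self.n_frames} frames cannot hold "
                f"{self.n_speed_changes + 1} epochs of at least "
                f"{self.min_epoch_intervals} intervals"
            )
        vmax = 2**self.bit_depth - 1
        if not 0 <= self.background_intensity <= vmax:
            raise ConfigError("background intensity outside bit depth range")
        if not 0 <= self.filament_intensity <= vmax:
            raise ConfigError("filament intensity outside bit depth range")
        if any(a <= 0 or b <= 0 for a, b in self.filament_sizes):
            raise ConfigError("filament sizes must be positive")
        if self.intensity_noise_sd < 0:
            raise ConfigError("intensity noise SD must be >= 0")


@dataclass
class GroundTruth:
    """Exact tracks and speeds behind a simulated dataset."""

    tracks: list[Track] = field(default_factory=list)
    true_speeds: list[VelocitySeries] = field(default_factory=list)
    change_frames: dict[str, list[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Velocity-track simulation
# ---------------------------------------------------------------------------

def _speed_profile(rng: np.random.Generator, cfg: TrackSimConfig,
                   n_intervals: int) -> np.ndarray:
    lo, hi = cfg.base_speed_range
    base = rng.uniform(lo, hi)
    profile = cfg.profile
    if profile == "mixed":
        profile = "periodic" if rng.random() < 0.5 else "constant"
    if profile == "constant":
        return np.full(n_intervals, base)
    period = rng.uniform(*cfg.periodic_period_frames)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_intervals)
    s = base * (1.0 + cfg.periodic_amplitude_frac
                * np.sin(2 * np.pi * t / period + phase))
    return np.maximum(s, 0.0)


def _integrate_positions(rng: np.random.Generator, speed: np.ndarray,
                         jitter_sd: float,
                         start: np.ndarray | None = None) -> np.ndarray:
    """Integrate a tip path: per-interval displacement of magnitude
    speed[i] along a heading that random-walks with the given SD."""
    n = len(speed) + 1
    theta0 = rng.uniform(0, 2 * np.pi)
    theta = theta0 + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, jitter_sd, n - 2))]
    )
    steps = speed[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    pos = np.empty((n, 2))
    pos[0] = np.zeros(2) if start is None else start
    pos[1:] = pos[0] + np.cumsum(steps, axis=0)
    return pos


def simulate_tracks(
    config: TrackSimConfig | None = None,
) -> list[tuple[Track, GroundTruth]]:
    """Generate noisy tracks paired with their ground truth.

    Each returned pair holds the noisy :class:`Track` (Gaussian position
    noise, sparse impulses) and a :class:`GroundTruth` with the clean
    track and the true per-interval speed.
    """
    cfg = config or TrackSimConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_tracks)
    out: list[tuple[Track, GroundTruth]] = []
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        speed = _speed_profile(rng, cfg, cfg.n_frames - 1)
        pos = _integrate_positions(rng, speed, cfg.heading_jitter_sd)
        noise = rng.normal(0.0, cfg.gaussian_pos_noise_sd, pos.shape)
        impulse_mask = rng.random(cfg.n_frames) < cfg.impulse_prob
        impulses = rng.normal(0.0, cfg.impulse_sd, pos.shape)
        noise[impulse_mask] = impulses[impulse_mask]
        frames = np.arange(cfg.n_frames)
        tid = f"sim{k:04d}"
        noisy = Track(tid, frames, pos[:, 0] + noise[:, 0],
                      pos[:, 1] + noise[:, 1])
        truth = GroundTruth(
            tracks=[Track(tid, frames, pos[:, 0], pos[:, 1])],
            true_speeds=[VelocitySeries(speed, variant="true", track_id=tid)],
        )
        out.append((noisy, truth))
    return out


# ---------------------------------------------------------------------------
# Image-sequence simulation
# ---------------------------------------------------------------------------

def _epoch_speeds(rng: np.random.Generator, cfg: ImageSimConfig
                  ) -> tuple[np.ndarray, list[int]]:
    """Piecewise-constant per-interval speed with n_speed_changes jumps.

    Epoch lengths are drawn constructively (minimum length plus a
    multinomial split of the slack) so every epoch spans at least
    ``min_epoch_intervals`` — long enough to survive the
    minimum-phase-length filter."""
    n_int = cfg.n_frames - 1
    min_len = cfg.min_epoch_intervals
    n_changes = cfg.n_speed_changes
    n_epochs = n_changes + 1
    slack = n_int - n_epochs * min_len
    lengths = min_len + rng.multinomial(slack, np.full(n_epochs, 1 / n_epochs))
    changes = np.cumsum(lengths)[:-1]
    edges = np.concatenate([[0], changes, [n_int]])
    speeds = rng.uniform(*cfg.speed_range, size=n_changes + 1)
    profile = np.empty(n_int)
    for s, e, v in zip(edges[:-1], edges[1:], speeds):
        profile[s:e] = v
    return profile, [int(c) for c in changes]


def _render_filament(canvas: np.ndarray, center: np.ndarray, theta: float,
                     half_len: float, half_wid: float,
                     intensity: float) -> None:
    """Max-blend an anti-aliased filled ellipse onto the canvas, wrapping
    toroidally at the borders."""
    h, w = canvas.shape
    margin = int(np.ceil(half_len)) + 2
    cx, cy = center
    xs = np.arange(int(np.floor(cx)) - margin, int(np.ceil(cx)) + margin + 1)
    ys = np.arange(int(np.floor(cy)) - margin, int(np.ceil(cy)) + margin + 1)
    xx, yy = np.meshgrid(xs, ys)
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(theta), np.sin(theta)
    u = (dx * c + dy * s) / half_len
    v = (-dx * s + dy * c) / half_wid
    rho = np.sqrt(u * u + v * v)
    # approximate signed distance to the ellipse boundary, in px
    dist = (rho - 1.0) * min(half_len, half_wid)
    cover = np.clip(0.5 - dist, 0.0, 1.0)
    vals = cover * intensity
    np.maximum.at(canvas, (yy % h, xx % w), vals)


def simulate_image_sequence(
    config: ImageSimConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render the synthetic IVMA movie and return (stack, ground truth).

    The stack is uint8 of shape (n_frames, height, width).  Ground-truth
    tracks record the *unwrapped* front-tip positions (the rendered
    position is taken modulo the image size), so true speeds follow from
    plain finite differences.  When ``out_dir`` is given, writes
    ``movie.tif`` (multi-page TIFF), ``truth_tracks.csv`` (tracks CSV)
    and ``truth_changes.csv`` (per-filament change frames and speeds).
    """
    cfg = config or ImageSimConfig()
    root = np.random.SeedSequence(cfg.seed)
    fil_streams = root.spawn(cfg.n_filaments)
    noise_rng = np.random.default_rng(root.spawn(1)[0])

    h, w = cfg.height, cfg.width
    stack = np.empty((cfg.n_frames, h, w), dtype=np.uint8)
    fg = cfg.filament_intensity - cfg.background_intensity

    truth = GroundTruth()
    rows = []
    filaments = []
    for k, ss in enumerate(fil_streams):
        rng = np.random.default_rng(ss)
        speed, changes = _epoch_speeds(rng, cfg)
        start = rng.uniform([0, 0], [w, h])
        tip = _integrate_positions(rng, speed, cfg.heading_jitter_sd, start)
        size = cfg.filament_sizes[rng.integers(len(cfg.filament_sizes))]
        tid = f"fil{k:02d}"
        frames = np.arange(cfg.n_frames)
        truth.tracks.append(Track(tid, frames, tip[:, 0], tip[:, 1]))
        truth.true_speeds.append(
            VelocitySeries(speed, variant="true", track_id=tid))
        truth.change_frames[tid] = changes
        edges = [0, *changes, cfg.n_frames - 1]
        for i, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
            rows.append({"track_id": tid, "epoch": i, "start_frame": s,
                         "end_frame": e, "speed": speed[s]})
        filaments.append((tip, size))

    for f in range(cfg.n_frames):
        canvas = np.zeros((h, w))
        for tip, (length, width_px) in filaments:
            if f == 0:
                heading = np.arctan2(tip[1, 1] - tip[0, 1],
                                     tip[1, 0] - tip[0, 0])
            else:
                heading = np.arctan2(tip[f, 1] - tip[f - 1, 1],
                                     tip[f, 0] - tip[f - 1, 0])
            # tip leads; the ellipse body trails behind it
            center = tip[f] - (length / 2.0) * np.array(
                [np.cos(heading), np.sin(heading)])
            _render_filament(canvas, center, heading, length / 2.0,
                             width_px / 2.0, fg)
        frame = cfg.background_intensity + canvas
        if cfg.intensity_noise_sd > 0:
            frame = frame + noise_rng.normal(0.0, cfg.intensity_noise_sd,
                                             frame.shape)
        stack[f] = np.clip(np.round(frame), 0, 2**cfg.bit_depth - 1
                           ).astype(np.uint8)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "movie.tif", stack)
        write_tracks_csv(truth.tracks, out / "truth_tracks.csv")
        pd.DataFrame(rows).to_csv(out / "truth_changes.csv", index=False)
    return stack, truth
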