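"""Frame-to-frame speed and velocity-signal reconstruction filters.

The sliding speed of a filament is the displacement of its tracked tip
divided by the elapsed time.  Position noise from tracking propagates into
this finite-difference signal, so a reconstruction filter is applied
before phases are identified.  Seven filters are provided: six classical
1D signal smoothers that act on the scalar speed series (moving average,
Gaussian, running median, Kolmogorov-Zurbenko, Savitzky-Golay, Spencer
15-point) and a Kalman filter that acts on the 2D positions with a
constant-velocity state-space model and derives speed from the filtered
velocity states.  The Kalman filter is the pipeline default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter, uniform_filter1d
from scipy.signal import savgol_filter

from .tracks import Calibration, Track, UNCALIBRATED

__all__ = [
    "VelocitySeries",
    "KalmanModel",
    "FilterSpec",
    "FilterSpecError",
    "InsufficientDataError",
    "compute_speed",
    "kalman_reconstruct",
    "kalman_filter_positions",
    "apply_filter",
    "BENCHMARK_FILTERS",
    "SPENCER_WEIGHTS",
]


class InsufficientDataError(ValueError):
    """Track or series too short for the requested operation."""


class FilterSpecError(ValueError):
    """Unknown filter kind or invalid filter parameters."""


@dataclass
class VelocitySeries:
    """Per-interval speed signal of one track.

    ``values[i]`` is the speed over the interval starting at frame
    ``start_frame + i`` (for gap-free tracks).  ``variant`` distinguishes
    the unfiltered finite-difference signal (``raw``), a reconstruction
    (``filtered``) and simulation ground truth (``true``).
    """

    values: np.ndarray
    start_frame: int = 0
    units: str = "px/frame"
    variant: str = "raw"
    track_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("VelocitySeries values must be 1D")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Raw speed
# ---------------------------------------------------------------------------

def compute_speed(track: Track, cal: Calibration = UNCALIBRATED) -> VelocitySeries:
    """Finite-difference speed: displacement between consecutive tracked
    points divided by the elapsed number of frames, scaled by the
    calibration.  Requires at least 2 points.
    """
    if len(track) < 2:
        raise InsufficientDataError(
            f"track {track.track_id!r}: need >= 2 points for a speed, "
            f"got {len(track)}"
        )
    df = np.diff(track.frames).astype(float)
    disp = np.hypot(np.diff(track.x), np.diff(track.y))
    return VelocitySeries(
        values=disp / df * cal.speed_scale,
        start_frame=int(track.frames[0]),
        units=cal.speed_units,
        variant="raw",
        track_id=track.track_id,
    )


# ---------------------------------------------------------------------------
# Kalman filter (constant-velocity model on positions)
# ---------------------------------------------------------------------------

@dataclass
class KalmanModel:
    """Constant-velocity state-space model for a tracked 2D point.

    State is (x, y, vx, vy); the transition matrix advances positions by
    the velocities over one frame.  Process noise follows the
    white-acceleration (discrete Wiener) form scaled by ``q`` (px^2 per
    frame); measurement noise is isotropic with variance ``r`` (px^2) per
    axis.  The initial state takes the first measured position with, by
    default, the first finite-difference displacement as velocity
    (two-point initialisation; ``init_velocity="zero"`` starts at rest
    instead), and a diagonal covariance ``p0``.
    """

    q: float = 0.05
    r: float = 1.0
    p0: float = 10.0
    dt: float = 1.0
    init_velocity: str = "difference"  # difference | zero

    def transition_matrix(self) -> np.ndarray:
        dt = self.dt
        return np.array(
            [
                [1.0, 0.0, dt, 0.0],
                [0.0, 1.0, 0.0, dt],
                [0.0, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )

    def measurement_matrix(self) -> np.ndarray:
        return np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])

    def process_noise(self) -> np.ndarray:
        dt, q = self.dt, self.q
        a, b, c = dt**4 / 4.0, dt**3 / 2.0, dt**2
        return q * np.array(
            [
                [a, 0.0, b, 0.0],
                [0.0, a, 0.0, b],
                [b, 0.0, c, 0.0],
                [0.0, b, 0.0, c],
            ]
        )

    def measurement_noise(self) -> np.ndarray:
        return self.r * np.eye(2)

    def validate(self) -> None:
        for name, m in (("Q", self.process_noise()), ("R", self.measurement_noise())):
            if not np.allclose(m, m.T):
                raise FilterSpecError(f"{name} not symmetric")
            if np.min(np.linalg.eigvalsh(m)) < -1e-12:
                raise FilterSpecError(f"{name} not positive semidefinite")


def kalman_filter_positions(
    track: Track, model: KalmanModel | None = None
) -> np.ndarray:
    """Run the forward Kalman filter over a track's positions.

    Returns the post-update state estimates, one row (x, y, vx, vy) per
    tracked point.  Missing frames (gaps) are bridged by pure prediction
    steps.  No backward smoothing pass is applied.
    """
    model = model or KalmanModel()
    model.validate()
    n = len(track)
    T = model.transition_matrix()
    Z = model.measurement_matrix()
    Q = model.process_noise()
    R = model.measurement_noise()

    if model.init_velocity == "difference" and n >= 2:
        gap = float(track.frames[1] - track.frames[0])
        v0 = np.array([track.x[1] - track.x[0], track.y[1] - track.y[0]]) / gap
    elif model.init_velocity in ("difference", "zero"):
        v0 = np.zeros(2)
    else:
        raise FilterSpecError(
            f"unknown init_velocity {model.init_velocity!r}"
        )
    state = np.array([track.x[0], track.y[0], v0[0], v0[1]])
    P = np.diag([model.p0] * 4)
    out = np.empty((n, 4))
    out[0] = state
    for i in range(1, n):
        # predict across the frame gap (usually 1 step)
        for _ in range(int(track.frames[i] - track.frames[i - 1])):
            state = T @ state
            P = T @ P @ T.T + Q
        z = np.array([track.x[i], track.y[i]])
        innov = z - Z @ state
        S = Z @ P @ Z.T + R
        K = P @ Z.T @ np.linalg.inv(S)
        state = state + K @ innov
        P = (np.eye(4) - K @ Z) @ P
        out[i] = state
    return out


def kalman_reconstruct(
    track: Track,
    model: KalmanModel | None = None,
    cal: Calibration = UNCALIBRATED,
) -> VelocitySeries:
    """Reconstruct the speed signal by Kalman-filtering the positions.

    Speed at interval i is the magnitude of the filtered velocity state
    after absorbing measurement i+1, so the output aligns with
    :func:`compute_speed` (same length, one value per interval).  The
    first interval carries the estimate after two updates.
    """
    if len(track) < 4:
        raise InsufficientDataError(
            f"track {track.track_id!r}: need >= 4 points for Kalman "
            f"reconstruction, got {len(track)}"
        )
    states = kalman_filter_positions(track, model)
    speed = np.hypot(states[1:, 2], states[1:, 3])
    return VelocitySeries(
        values=speed * cal.speed_scale,
        start_frame=int(track.frames[0]),
        units=cal.speed_units,
        variant="filtered",
        track_id=track.track_id,
    )


# ---------------------------------------------------------------------------
# Scalar signal filters
# ---------------------------------------------------------------------------

#: classical 15-point Spencer smoothing weights (sum to 1)
SPENCER_WEIGHTS = (
    np.array([-3, -6, -5, 3, 21, 46, 67, 74, 67, 46, 21, 3, -5, -6, -3], float)
    / 320.0
)

_FILTER_KINDS = ("mean", "gaussian", "median", "kz", "sg", "spencer", "kalman")


@dataclass
class FilterSpec:
    """A named smoothing filter plus its parameters.

    kind: one of mean | gaussian | median | kz | sg | spencer | kalman.
    Window lengths must be odd and >= 3.  ``kalman`` is special: it
    consumes positions, not a scalar series, via
    :func:`kalman_reconstruct`; its parameters are q and r.
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _FILTER_KINDS:
            raise FilterSpecError(
                f"unknown filter kind {self.kind!r}; expected one of {_FILTER_KINDS}"
            )
        w = self.params.get("window")
        if w is not None and (w < 3 or w % 2 == 0):
            raise FilterSpecError(f"window must be odd and >= 3, got {w}")
        sigma = self.params.get("sigma")
        if sigma is not None and sigma <= 0:
            raise FilterSpecError(f"sigma must be > 0, got {sigma}")

    def window_length(self) -> int:
        """Effective support length, used for length preconditions."""
        if self.kind == "spencer":
            return 15
        if self.kind == "gaussian":
            return 2 * int(4 * self.params.get("sigma", 2.0)) + 1
        if self.kind == "kalman":
            return 4
        return int(self.params.get("window", 9))


#: benchmark defaults for the seven filters (symmetric odd windows,
#: roughly one second of signal at 10 fps)
BENCHMARK_FILTERS: dict[str, FilterSpec] = {
    "kalman": FilterSpec("kalman", {"q": 0.05, "r": 1.0}),
    "mean": FilterSpec("mean", {"window": 9}),
    "gaussian": FilterSpec("gaussian", {"sigma": 2.0}),
    "median": FilterSpec("median", {"window": 9}),
    "kz": FilterSpec("kz", {"window": 5, "iterations": 3}),
    "sg": FilterSpec("sg", {"window": 9, "order": 2}),
    "spencer": FilterSpec("spencer", {}),
}


def _reflect_convolve(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-length convolution with reflect padding (symmetric kernels)."""
    half = len(kernel) // 2
    padded = np.pad(values, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def apply_filter(series: VelocitySeries, spec: FilterSpec) -> VelocitySeries:
    """Apply a scalar smoothing filter to a speed series.

    All windowed filters use reflect padding at the edges and return a
    series of the same length.  The ``kalman`` kind is rejected here
    because it operates on positions (use :func:`kalman_reconstruct`).
    """
    if spec.kind == "kalman":
        raise FilterSpecError(
            "the Kalman filter consumes positions; use kalman_reconstruct()"
        )
    v = series.values
    wlen = spec.window_length()
    if len(v) < wlen:
        raise InsufficientDataError(
            f"series of length {len(v)} shorter than filter support {wlen}"
        )
    p = spec.params
    if spec.kind == "mean":
        out = uniform_filter1d(v, size=int(p.get("window", 9)), mode="reflect")
    elif spec.kind == "gaussian":
        out = gaussian_filter1d(v, sigma=float(p.get("sigma", 2.0)),
                                mode="reflect", truncate=4.0)
    elif spec.kind == "median":
        out = median_filter(v, size=int(p.get("window", 9)), mode="reflect")
    elif spec.kind == "kz":
        out = v
        for _ in range(int(p.get("iterations", 3))):
            out = uniform_filter1d(out, size=int(p.get("window", 5)),
                                   mode="reflect")
    elif spec.kind == "sg":
        out = savgol_filter(v, window_length=int(p.get("window", 9)),
                            polyorder=int(p.get("order", 2)), mode="mirror")
    elif spec.kind == "spencer":
        out = _reflect_convolve(v, SPENCER_WEIGHTS)
    else:  # pragma: no cover - caught in FilterSpec
        raise FilterSpecError(f"unknown filter kind {spec.kind!r}")
    return replace(series, values=out, variant="filtered")
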