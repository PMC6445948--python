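"""Filament track data model and I/O.

Tracks are ordered sequences of 2D tip positions, one position per video
frame, as produced by manual or automatic particle trackers.  Two on-disk
formats are supported: the MTrackJ data file (``.mdf``, the text format of
the ImageJ manual-tracking plugin) and a generic ``track_id,frame,x,y``
CSV.  All readers normalise to the same in-memory :class:`Track`.

Coordinates use the image convention (origin top-left, x rightward,
y downward) in pixels.  Frames are 0-based internally; MDF files count
time points from 1 and are shifted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrackPoint",
    "Track",
    "Calibration",
    "TrackFormatError",
    "TrackValidationError",
    "read_mdf",
    "write_mdf",
    "read_tracks_csv",
    "write_tracks_csv",
]


class TrackFormatError(ValueError):
    """The file does not conform to the expected track format."""


class TrackValidationError(ValueError):
    """Parsed track data violates an invariant (duplicate frame, NaN, ...)."""


@dataclass(frozen=True)
class TrackPoint:
    """A single tracked tip position: frame index plus (x, y) in pixels."""

    frame: int
    x: float
    y: float


@dataclass
class Calibration:
    """Spatial and temporal scale of the recording.

    Parameters
    ----------
    pixel_size : float
        Micrometres per pixel.  Defaults to 1.0, in which case velocities
        stay in pixel units.
    frame_interval : float
        Seconds per frame.  Defaults to 0.1 s (10 fps), a typical IVMA
        acquisition rate; with the default pixel size velocities are
        reported per frame rather than per second.
    """

    pixel_size: float = 1.0
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise TrackValidationError(
                "pixel_size and frame_interval must be strictly positive, got "
                f"{self.pixel_size}, {self.frame_interval}"
            )

    @property
    def calibrated(self) -> bool:
        return self.pixel_size != 1.0

    @property
    def speed_units(self) -> str:
        """Unit label for speeds computed under this calibration."""
        return "um/s" if self.calibrated else "px/frame"

    @property
    def speed_scale(self) -> float:
        """Factor converting px/frame to the output unit."""
        if self.calibrated:
            return self.pixel_size / self.frame_interval
        return 1.0


#: calibration leaving everything in pixel/frame units
UNCALIBRATED = Calibration(pixel_size=1.0, frame_interval=1.0)


@dataclass
class Track:
    """One filament tip trajectory.

    Positions are stored as parallel arrays ``frames`` (0-based, strictly
    increasing integers), ``x`` and ``y`` (pixels).  Gaps (missing frames)
    are allowed; velocity computations divide displacement by the elapsed
    number of frames.
    """

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise TrackValidationError(
                f"track {self.track_id!r}: frames/x/y lengths differ"
            )
        if len(self.frames) and self.frames.min() < 0:
            raise TrackValidationError(
                f"track {self.track_id!r}: negative frame index"
            )
        if np.any(np.diff(self.frames) == 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: duplicate frame index"
            )
        if np.any(np.diff(self.frames) < 0):
            order = np.argsort(self.frames, kind="stable")
            self.frames = self.frames[order]
            self.x = self.x[order]
            self.y = self.y[order]
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite coordinate"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> list[TrackPoint]:
        return [
            TrackPoint(int(f), float(px), float(py))
            for f, px, py in zip(self.frames, self.x, self.y)
        ]

    @classmethod
    def from_points(cls, track_id: str, points: Iterable[TrackPoint]) -> "Track":
        pts = sorted(points, key=lambda p: p.frame)
        return cls(
            track_id=track_id,
            frames=np.array([p.frame for p in pts], dtype=np.int64),
            x=np.array([p.x for p in pts]),
            y=np.array([p.y for p in pts]),
        )


# ---------------------------------------------------------------------------
# MTrackJ MDF data files
# ---------------------------------------------------------------------------

def read_mdf(path: str | Path) -> list[Track]:
    """Read tracks from an MTrackJ data file.

    Only the ``Track`` and ``Point`` records are consumed; of each point
    record the x, y and t columns are used.  The 1-based t column becomes
    the 0-based frame index.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("MTrackJ"):
        raise TrackFormatError(
            f"{path}: not an MTrackJ data file (missing 'MTrackJ' header)"
        )
    tracks: list[Track] = []
    cur_id: str | None = None
    cur_pts: list[TrackPoint] = []

    def flush() -> None:
        nonlocal cur_id, cur_pts
        if cur_id is not None:
            frames = [p.frame for p in cur_pts]
            if len(set(frames)) != len(frames):
                raise TrackValidationError(
                    f"{path}: duplicate frame in track {cur_id}"
                )
            tracks.append(Track.from_points(cur_id, cur_pts))
        cur_id, cur_pts = None, []

    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if not fields:
            continue
        kind = fields[0]
        if kind == "Track":
            flush()
            cur_id = fields[1] if len(fields) > 1 else str(len(tracks) + 1)
        elif kind == "Point":
            if cur_id is None:
                raise TrackFormatError(
                    f"{path}:{lineno}: Point record outside any Track"
                )
            # Point <pid> <x> <y> <z> <t> <c>
            try:
                x, y, t = float(fields[2]), float(fields[3]), float(fields[5])
            except (IndexError, ValueError) as exc:
                raise TrackFormatError(
                    f"{path}:{lineno}: malformed Point record: {line!r}"
                ) from exc
            cur_pts.append(TrackPoint(frame=int(round(t)) - 1, x=x, y=y))
        # other record kinds (Assembly, Cluster, Offset, ...) are ignored
    flush()
    return tracks


def write_mdf(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks as a minimal MTrackJ data file (frames back to 1-based)."""
    out = ["MTrackJ 1.5.1 Data File", "Assembly 1", "Cluster 1"]
    for tr in tracks:
        out.append(f"Track {tr.track_id}")
        for i, (f, x, y) in enumerate(zip(tr.frames, tr.x, tr.y), start=1):
            out.append(f"Point {i} {x:.6f} {y:.6f} 1.0 {int(f) + 1}.0 1")
    out.append("End of MTrackJ Data File")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Generic CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["track_id", "frame", "x", "y"]


def read_tracks_csv(path: str | Path) -> list[Track]:
    """Read tracks from a ``track_id,frame,x,y`` CSV (column order free)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing column(s) {missing}")
    if len(df) and (df["x"].isna().any() or df["y"].isna().any()):
        raise TrackValidationError(f"{path}: NaN coordinate")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame", kind="stable")
        tracks.append(
            Track(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                x=grp["x"].to_numpy(dtype=np.float64),
                y=grp["y"].to_numpy(dtype=np.float64),
            )
        )
    return tracks


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks to CSV, lossless to well beyond 1e-6 px."""
    frames = np.concatenate([t.frames for t in tracks]) if tracks else []
    df = pd.DataFrame(
        {
            "track_id": np.concatenate(
                [np.repeat(t.track_id, len(t)) for t in tracks]
            )
            if tracks
            else [],
            "frame": frames,
            "x": np.concatenate([t.x for t in tracks]) if tracks else [],
            "y": np.concatenate([t.y for t in tracks]) if tracks else [],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
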