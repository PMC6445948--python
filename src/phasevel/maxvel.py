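"""Maximum velocity from a phase-velocity distribution.

Pooling the phases of every filament in an image sequence gives a
distribution of phase velocities.  The maximum sliding velocity is
defined through a top-fraction rule: sort phase velocities in decreasing
order and accumulate from the fastest until the running sum reaches a
fraction (default 10%) of the total sum

    v_sum = sum_i v_i ,

then average the accumulated velocities.  The phase that crosses the
threshold is included, so at least one phase is always selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phases import Phase, PhaseSet

__all__ = [
    "MaxVelocityResult",
    "NoPhasesError",
    "DegenerateVelocitiesError",
    "max_velocity",
    "phase_velocity_distribution",
]


class NoPhasesError(ValueError):
    """No phases available: every phase was dropped or none were found."""


class DegenerateVelocitiesError(ValueError):
    """All phase velocities are zero; the top-fraction rule is undefined."""


@dataclass
class MaxVelocityResult:
    """Outcome of the top-fraction maximum-velocity rule."""

    v_max: float
    v_sum: float
    fraction: float
    selected: list[Phase]
    n_phases_total: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _sorted_phases(phase_set: PhaseSet) -> list[Phase]:
    # decreasing velocity; ties broken by earlier start frame, then track id
    return sorted(
        phase_set.phases,
        key=lambda p: (-p.mean_velocity, p.start, str(p.track_id)),
    )


def max_velocity(
    phase_set: PhaseSet,
    fraction: float = 0.10,
    duration_weighted: bool = False,
    include_crossing: bool = True,
) -> MaxVelocityResult:
    """Apply the top-fraction rule to a pooled phase set.

    Parameters
    ----------
    fraction : proportion of ``v_sum`` the selected fastest phases must
        reach (default 0.10).
    duration_weighted : average the selected velocities weighted by phase
        duration instead of the default unweighted mean.
    include_crossing : include the phase whose addition crosses the
        threshold (default).  With ``False`` the selection stops just
        below the threshold but always keeps at least one phase.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(phase_set) == 0:
        raise NoPhasesError("phase set is empty")
    velocities = phase_set.velocities()
    if np.any(velocities < 0):
        raise ValueError("negative phase velocity")
    v_sum = float(velocities.sum())
    if v_sum == 0.0:
        raise DegenerateVelocitiesError("all phase velocities are zero")

    ordered = _sorted_phases(phase_set)
    threshold = fraction * v_sum
    selected: list[Phase] = []
    cum = 0.0
    for ph in ordered:
        if cum >= threshold and selected:
            break
        if not include_crossing and selected and cum + ph.mean_velocity > threshold:
            break
        selected.append(ph)
        cum += ph.mean_velocity
    vals = np.array([p.mean_velocity for p in selected])
    if duration_weighted:
        w = np.array([p.duration_frames for p in selected], dtype=float)
        v_max = float(np.average(vals, weights=w))
    else:
        v_max = float(vals.mean())
    return MaxVelocityResult(
        v_max=v_max,
        v_sum=v_sum,
        fraction=fraction,
        selected=selected,
        n_phases_total=len(phase_set),
    )


def phase_velocity_distribution(phase_set: PhaseSet) -> pd.DataFrame:
    """Phase records sorted by decreasing velocity, ready for export or
    histogramming.  Columns: track_id, start, end, duration_frames,
    duration_s, mean_velocity, sd_velocity."""
    ordered = _sorted_phases(phase_set)
    return pd.DataFrame(
        {
            "track_id": [p.track_id for p in ordered],
            "start": [p.start for p in ordered],
            "end": [p.end for p in ordered],
            "duration_frames": [p.duration_frames for p in ordered],
            "duration_s": [p.duration_s for p in ordered],
            "mean_velocity": [p.mean_velocity for p in ordered],
            "sd_velocity": [p.sd_velocity for p in ordered],
        }
    )
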