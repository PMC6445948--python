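"""Split-and-merge identification of homogeneous velocity phases.

Filament sliding in the motility assay is heterogeneous: stretches of
steady movement alternate with slow-downs, stops and noisy episodes.  A
phase is a contiguous stretch of the reconstructed velocity signal with
statistically homogeneous velocity.  The procedure:

1. *Split*: smooth the signal with a 1D Gaussian (sigma in signal
   samples, i.e. frame intervals) and cut at every local maximum of the
   smoothed signal, yielding fine fractions.
2. *Merge*: walk left to right; Welch's t-test compares the values of the
   current segment with the next fraction.  If they are not significantly
   different (p > alpha) the fraction is absorbed; otherwise the segment
   is closed as a phase and the fraction starts a new segment.
3. *Prune*: phases shorter than a minimum duration (default 10 frames,
   one second at 10 fps) are discarded as outliers.

The smoothed signal serves only to place split points; t-tests and phase
statistics use the (reconstructed) input values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .filters import InsufficientDataError, VelocitySeries

__all__ = [
    "PhaseSegParams",
    "Phase",
    "PhaseSet",
    "split_at_local_maxima",
    "merge_fractions",
    "drop_short_phases",
    "identify_phases",
]


@dataclass
class PhaseSegParams:
    """Tuning knobs of the split-and-merge segmentation.

    smooth_sigma : SD of the Gaussian pre-filter in frame intervals
        (default 3).  Only affects where splits are placed.
    alpha : significance level of the merge t-test (default 0.05);
        fractions merge when p > alpha.
    min_phase_frames : minimum phase duration in frames (default 10).
    frame_interval : seconds per frame, for durations in seconds.
    """

    smooth_sigma: float = 3.0
    alpha: float = 0.05
    min_phase_frames: int = 10
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.smooth_sigma <= 0:
            raise ValueError(f"smooth_sigma must be > 0, got {self.smooth_sigma}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_phase_frames < 1:
            raise ValueError(
                f"min_phase_frames must be >= 1, got {self.min_phase_frames}"
            )


@dataclass
class Phase:
    """One homogeneous-velocity segment, half-open on interval indices."""

    start: int
    end: int
    mean_velocity: float
    sd_velocity: float
    frame_interval: float = 0.1
    track_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty phase [{self.start}, {self.end})")

    @property
    def duration_frames(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return self.duration_frames * self.frame_interval


@dataclass
class PhaseSet:
    """Ordered, non-overlapping phases, possibly pooled across tracks."""

    phases: list[Phase] = field(default_factory=list)
    source: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    def velocities(self) -> np.ndarray:
        return np.array([p.mean_velocity for p in self.phases])

    def extend(self, other: "PhaseSet") -> None:
        self.phases.extend(other.phases)
        for s in other.source:
            if s not in self.source:
                self.source.append(s)


def split_at_local_maxima(
    series: VelocitySeries, params: PhaseSegParams | None = None
) -> list[int]:
    """Gaussian-smooth the series and return the indices of its interior
    local maxima, which partition [0, n) into fractions.

    A maximum at i satisfies smoothed[i-1] < smoothed[i] >= smoothed[i+1];
    a plateau therefore contributes only its first index.  Smoothing uses
    reflect padding with the kernel truncated at 4 sigma.
    """
    params = params or PhaseSegParams()
    v = series.values
    if len(v) < 3:
        raise InsufficientDataError(
            f"series of length {len(v)} too short to split (need >= 3)"
        )
    s = gaussian_filter1d(v, sigma=params.smooth_sigma, mode="reflect",
                          truncate=4.0)
    interior = np.arange(1, len(s) - 1)
    is_max = (s[interior - 1] < s[interior]) & (s[interior] >= s[interior + 1])
    return [int(i) for i in interior[is_max]]


def _make_phase(
    series: VelocitySeries, start: int, end: int, params: PhaseSegParams
) -> Phase:
    seg = series.values[start:end]
    return Phase(
        start=start,
        end=end,
        mean_velocity=float(np.mean(seg)),
        sd_velocity=float(np.std(seg, ddof=1)) if len(seg) > 1 else 0.0,
        frame_interval=params.frame_interval,
        track_id=series.track_id,
    )


def merge_fractions(
    series: VelocitySeries,
    boundaries: list[int],
    params: PhaseSegParams | None = None,
) -> PhaseSet:
    """Sequentially merge adjacent fractions whose values do not differ
    significantly (Welch two-sample t-test, p > alpha).

    The current segment grows by absorbing fractions until a significant
    difference closes it as a phase; the rejected fraction then starts
    the next segment.  Fractions with fewer than 2 values carry no
    variance information and are absorbed unconditionally.
    """
    params = params or PhaseSegParams()
    n = len(series.values)
    edges = [0, *boundaries, n]
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError(f"invalid boundaries {boundaries} for length {n}")

    phases: list[Phase] = []
    cur_start = 0
    cur_end = edges[1]
    for nxt_start, nxt_end in zip(edges[1:-1], edges[2:]):
        cur = series.values[cur_start:cur_end]
        nxt = series.values[nxt_start:nxt_end]
        scale = max(1.0, abs(float(np.mean(cur))))
        if len(nxt) < 2 or len(cur) < 2:
            p = 1.0  # degenerate fraction: merge unconditionally
        elif abs(float(np.mean(cur) - np.mean(nxt))) <= 1e-9 * scale:
            p = 1.0  # numerically identical (e.g. noise-free signals)
        else:
            p = stats.ttest_ind(cur, nxt, equal_var=False).pvalue
            if np.isnan(p):  # zero variance in both samples, equal means
                p = 1.0 if np.mean(cur) == np.mean(nxt) else 0.0
        if p > params.alpha:
            cur_end = nxt_end
        else:
            phases.append(_make_phase(series, cur_start, cur_end, params))
            cur_start, cur_end = nxt_start, nxt_end
    phases.append(_make_phase(series, cur_start, cur_end, params))
    return PhaseSet(
        phases=phases,
        source=[series.track_id] if series.track_id is not None else [],
    )


def drop_short_phases(
    phase_set: PhaseSet, params: PhaseSegParams | None = None
) -> PhaseSet:
    """Remove phases shorter than the minimum duration; survivors are
    kept as-is (no re-merging across the removed stretches)."""
    params = params or PhaseSegParams()
    return PhaseSet(
        phases=[
            p for p in phase_set.phases
            if p.duration_frames >= params.min_phase_frames
        ],
        source=list(phase_set.source),
    )


def identify_phases(
    series: VelocitySeries, params: PhaseSegParams | None = None
) -> PhaseSet:
    """Full split-and-merge segmentation of one velocity series."""
    params = params or PhaseSegParams()
    boundaries = split_at_local_maxima(series, params)
    merged = merge_fractions(series, boundaries, params)
    return drop_short_phases(merged, params)
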