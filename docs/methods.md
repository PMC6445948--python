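# Methods

## Velocity signal and calibration

A track is an ordered sequence of 2D tip positions (x, y) in pixels,
one per video frame, with gaps allowed. The raw speed over the interval
between consecutive tracked points is the Euclidean displacement divided
by the elapsed number of frames. With a calibration (pixel size in
μm/px, frame interval in s/frame) speeds are scaled to μm/s; with the
default pixel size of 1 the output stays in px/frame. Tips rather than
centroids are assumed to be tracked, which reduces shape-induced
position noise for elongated filaments.

Coordinates follow the image convention (origin top-left, y downward).
Frames are 0-based internally; MTrackJ data files count time points
from 1 and are shifted on read and write.

## Kalman reconstruction

The default reconstruction filters the positions, not the scalar speed
signal, with a linear-Gaussian state-space model

    α_{t+1} = T α_t + w_t ,   z_t = Z α_t + ε_t ,

state α = (x, y, ẋ, ẏ), constant-velocity transition T (dt = 1 frame),
measurement matrix Z selecting the positions. Process noise follows the
discrete white-acceleration form Q = q·[[dt⁴/4, dt³/2], [dt³/2, dt²]]
per axis with **q = 0.05 px²/frame**; measurement noise is isotropic
with **r = 1 px²** per axis. These defaults balance responsiveness to
genuine speed changes against suppression of ~1 px tracking noise at
10 fps; both are exposed on the API and CLI.

The filter runs forward only (no smoothing pass). Missing frames are
bridged by pure prediction steps. The initial state takes the first
measured position and, by default, the first finite-difference
displacement as velocity (`init_velocity="difference"`); a zero-velocity
start (`"zero"`) is available but produces a ~10-interval startup
transient that biases the first phase's mean velocity low, which is why
two-point initialisation is the default. On a noiseless
constant-velocity track the default initialisation reproduces the true
speed exactly from the first interval.

Speed at interval i is the magnitude of the velocity state after
absorbing measurement i+1, so the filtered series aligns one-to-one
with the raw finite-difference series.

## Scalar comparison filters

Six classical smoothers operate on the raw speed series, all with
odd symmetric supports of roughly one second at 10 fps and reflect
padding at the edges: moving average (window 9), Gaussian (σ = 2
intervals, kernel truncated at 4σ), running median (window 9),
Kolmogorov–Zurbenko (window 5, 3 iterations), Savitzky–Golay (window 9,
order 2), and the fixed 15-point Spencer filter. All linear kernels have
unit DC gain. Reconstruction quality is scored per track by
R² = 1 − SSE_filter/SSE_total, where SSE_total is the squared deviation
of the raw speed from the true speed and SSE_filter that of the filtered
speed; R² may be negative when a filter does worse than no filtering.

## Split-and-merge phase identification

The reconstructed series is pre-smoothed with a 1D Gaussian of
**σ = 3 frame intervals** (reflect padding, 4σ truncation) solely to
place split points: every interior local maximum of the smoothed signal
(strictly rising on the left, non-rising on the right, so a plateau
contributes its first index) becomes a fraction boundary. The σ value
follows the method's published description, whose unit label ("px") for
a temporal filter we read as signal samples.

Fractions are then merged left to right: a Welch two-sample t-test
compares the *reconstructed* values of the current segment and the next
fraction; at p > α (default **α = 0.05**) the fraction is absorbed,
otherwise the segment closes as a phase and the rejected fraction starts
the next segment. Welch's unequal-variance form is used because phases
differ in velocity variability by construction. Fractions with fewer
than two values carry no variance information and are absorbed
unconditionally, and a mean difference below 1e-9 (relative) is treated
as a tie and merged, so that numerically constant signals do not
fragment on floating-point noise. Phases shorter than
**min_phase_frames = 10** (one second at 10 fps) are discarded; the
survivors are not re-merged across the removed stretches. No
multiple-testing correction is applied across the sequential t-tests,
by design.

Segmentation accuracy is limited by two structural facts worth knowing:
local maxima of a σ-smoothed noise signal occur on average only every
≈ 4πσ/√3 ≈ 22 intervals, and a speed step smeared by the σ = 3
pre-filter spreads over ±2σ = ±6 intervals, so phase boundaries carry a
systematic uncertainty of several intervals and a low-velocity valley
between two faster phases is often bridged by a single mixed fraction.
Phase *means* of the fastest phases are nevertheless accurate, because
merging rejects mixed fractions at the ends of fast plateaus; the
top-fraction v_max statistic inherits that robustness, which is the
point of the design.

## Maximum velocity

Phases from all tracks of a sequence are pooled. Phase velocities are
sorted in decreasing order (ties broken by earlier start frame, then
track id) and accumulated until the running sum reaches
**fraction = 0.10** of v_sum = Σ vᵢ; the phase that crosses the
threshold is included, so at least one phase is always selected. v_max
is the unweighted mean of the selected velocities; a duration-weighted
mean is available but off by default, as is excluding the
threshold-crossing phase. The fraction is a free parameter, so a
top-5 % variant is expressible.

## Synthetic data

**Velocity tracks** (filter benchmark): 330 tracks of 100 frames. Each
track draws a base speed uniformly from 2–8 px/frame; half the tracks
(in the default `mixed` profile) modulate it sinusoidally with relative
amplitude 0.3 and a period of 10–30 frames, emulating the periodic
velocity fluctuations of real filaments; the rest are constant. The
heading random-walks with SD 0.05 rad/frame. Tip positions get Gaussian
noise of SD 1 px per axis; with probability 0.08 per point the noise is
replaced by an impulse of SD 5 px, standing in for gross tracking
blunders. These noise and profile magnitudes are the package's declared
benchmark conditions — chosen once as representative of manually tracked
IVMA data at 10 fps — not measurements of any particular dataset. Under
them the Kalman filter attains mean R² ≈ 0.88–0.90 and ranks first among
the seven filters across independent seed batches.

**Image sequences** (end-to-end validation): 100 frames, 8-bit,
700 × 700 px, background intensity 80, with 30 elliptical filaments of
intensity 130 and sizes 17 × 3 or 8 × 3 px (chosen uniformly), gliding
at 2–8 px/frame with heading jitter 0.08 rad/frame. Each filament
changes speed twice; epoch lengths are drawn constructively (minimum 10
intervals plus a multinomial split of the slack) so every speed epoch
can survive the minimum-phase-length filter. Per-pixel Gaussian noise of
SD 15 grey levels is added and clipped to [0, 255] — the noise magnitude
is read as intensity levels, since additive image noise measured in px
would be dimensionally inconsistent. Filaments are rendered as
anti-aliased rigid ellipses trailing their tracked front tip and wrap
toroidally at the borders so all 30 stay visible; the ground-truth
tracks store *unwrapped* tip positions, so true speeds follow from plain
finite differences. All randomness flows from one seed through numpy
`SeedSequence` spawning: one child stream per filament/track plus one
for pixel noise.

What the simulations do not emulate: filament bending, crossing and
breaking, photobleaching, PSF blur, and detection/segmentation errors of
automatic trackers. Passing tests therefore validate the velocity
pipeline given tracks, not tracking itself.

## Numerical choices and degenerate inputs

- Tracks shorter than 2 points cannot yield a speed; shorter than 4,
  no Kalman reconstruction; series shorter than a filter's support are
  rejected (the benchmark skips and counts them).
- The pipeline skips too-short tracks with a warning and raises a
  no-phases error (CLI exit code 3) when nothing survives the
  minimum-length filter.
- An all-zero phase-velocity set makes the top-fraction rule undefined
  and is rejected.
- R² requires the raw signal to differ from the truth somewhere;
  otherwise the measure is undefined and an error is raised.
- CSV round-trips preserve coordinates to better than 1e-6 px (9
  significant digits).

## Problem sizes

The shipped validation runs use the study-scale conditions throughout:
the full 330-track benchmark (five seed batches for the ranking check)
and the full 100-frame, 30-filament image sequence; smaller sizes appear
only in unit tests of mechanics.
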