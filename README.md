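# phasevel

Maximum sliding velocity of actin filaments in the *in vitro* motility
assay (IVMA), computed from filament-tip tracking data.

In the IVMA, surface-bound myosin motors propel fluorescently labelled
actin filaments across a coverslip; the filament sliding velocity is the
assay's readout and reports on myosin type, ATPase rate and motor
density. Filament movement is heterogeneous — steady runs alternate with
slow-downs and stops — and tracking noise corrupts the frame-to-frame
velocity signal, so the *maximum* velocity is hard to estimate well.
Simple top-percentile rules on raw per-frame velocities underestimate
it.

`phasevel` implements a three-stage phase-velocity method:

1. **Signal reconstruction.** Per track, the finite-difference speed
   v_t = ‖p_{t+1} − p_t‖/Δt is denoised by a Kalman filter with a
   constant-velocity state-space model on the 2D tip positions, state
   α_t = (x_t, y_t, ẋ_t, ẏ_t); speed is taken from the filtered velocity
   states. Six classical scalar smoothers (moving average, Gaussian,
   median, Kolmogorov–Zurbenko, Savitzky–Golay, Spencer 15-point) are
   included for comparison, scored by
   R² = 1 − SSE_filter/SSE_total against simulated ground truth.
2. **Phase identification.** The reconstructed signal is partitioned
   into phases of statistically homogeneous velocity by split-and-merge:
   split at all local maxima of a Gaussian-smoothed copy (σ = 3
   intervals), sequentially merge adjacent fractions whose values a
   Welch t-test cannot distinguish (p > 0.05), and drop phases shorter
   than 10 frames (1 s at 10 fps).
3. **Maximum velocity.** Phases of all filaments in a sequence are
   pooled; with v_sum = Σᵢ vᵢ over the N phase velocities, the fastest
   phases are accumulated until their sum reaches 10 % of v_sum, and
   v_max is their unweighted mean.

Simulation modules generate the two kinds of synthetic data the method
is validated on: noisy 2D velocity tracks with known speed profiles (for
the filter benchmark) and an 8-bit fluorescence-like movie of elliptical
filaments with exact ground truth (for the end-to-end pipeline).

## Worked example

```sh
python examples/01_max_velocity_pipeline.py
```

```
phases found: 105 across 30 tracks
v_sum  =  553.41 px/frame  (sum of all phase velocities)
v_max  =    7.73 px/frame  (mean of the 8 fastest phases reaching 10% of v_sum)
fastest simulated speed: 7.91 px/frame
```

Thirty simulated filaments glide at 2–8 px/frame, each changing speed
twice; the pipeline segments their velocity signals into 105 phases and
averages the fastest fraction into v_max = 7.73 px/frame, just below the
single fastest programmed speed (7.91) because it averages a whole top
fraction of phases rather than chasing one extreme value.

The same pipeline runs from the shell on MTrackJ `.mdf` or generic
`track_id,frame,x,y` CSV exports:

```sh
phasevel run --input tracks.mdf --pixel-size 0.16 --frame-interval 0.1 \
    --out results/
phasevel benchmark --n 330 --seed 42 --out bench.csv
phasevel simulate-images --seed 42 --out movie/
```

With a pixel size (μm/px) and frame interval (s/frame) supplied,
velocities are reported in μm/s; otherwise in px/frame.

See `examples/` for the filter benchmark, single-track phase
segmentation and movie simulation, each printing and explaining its
numbers.

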