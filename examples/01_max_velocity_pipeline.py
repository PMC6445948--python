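"""Full pipeline on simulated filament tracks.

Builds a small synthetic movie's ground-truth tip tracks (30 gliding
filaments, speeds 2-8 px/frame, two speed changes each), runs
Kalman reconstruction -> phase identification -> top-10% rule, and
prints the maximum sliding velocity of the sequence.
"""

from phasevel import (
    Calibration,
    ImageSimConfig,
    PipelineConfig,
    run_pipeline,
    simulate_image_sequence,
)

_, truth = simulate_image_sequence(ImageSimConfig(seed=42))

config = PipelineConfig(calibration=Calibration(pixel_size=1.0,
                                                frame_interval=1.0))
result = run_pipeline(truth.tracks, config)

mv = result.max_velocity
print(f"phases found: {mv.n_phases_total} across {result.n_tracks} tracks")
print(f"v_sum  = {mv.v_sum:7.2f} px/frame  (sum of all phase velocities)")
print(f"v_max  = {mv.v_max:7.2f} px/frame  "
      f"(mean of the {mv.n_selected} fastest phases reaching "
      f"{mv.fraction:.0%} of v_sum)")
best = max(ts.values.max() for ts in truth.true_speeds)
print(f"fastest simulated speed: {best:.2f} px/frame")
# v_max sits just below the single fastest filament because it averages
# the whole fastest fraction of phases, making it robust to outliers.
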