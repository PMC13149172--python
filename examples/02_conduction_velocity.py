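"""Map a propagating wavefront and estimate conduction velocity.

Renders a 64x64-pixel planar wave sweeping the field at 8.5 cm/s
(0.01 cm/pixel, 100 fps, SNR 20), builds the per-pixel activation-time
map for one beat, and reads the wavefront speed back from local plane
fits of the activation surface.
"""

import numpy as np

from cardiomap.io import extract_trace
from cardiomap.mapping import beat_window, compute_activation_map, estimate_cv
from cardiomap.recovery import wt_voltage_template
from cardiomap.synth import PropagationModel, RhythmScript, SimulationConfig, simulate_recording
from cardiomap.transients import analyze_trace

cfg = SimulationConfig(
    shape=(64, 64),
    pixel_pitch=0.01,
    duration=10.0,
    waveform=wt_voltage_template(),
    rhythm=RhythmScript(base_frequency=0.67),
    propagation=PropagationModel(pattern="planar", speed=8.5, angle_deg=25.0),
    seed=3,
)
movie, truth = simulate_recording(cfg)

beats, _, _ = analyze_trace(extract_trace(movie, "global"))
times = np.array([b.activation_time for b in beats])
amap = compute_activation_map(movie, beat_window(times, 1, movie.duration), beat_index=1)
est = estimate_cv(amap)

print(f"quality pixels: {100*est.quality_fraction:.1f}%  local plane fits: {est.n_local}")
print(f"median CV: {est.median_cv:.2f} cm/s  mean CV: {est.mean_cv:.2f} cm/s  (scripted 8.5)")
# The median of local speeds is the headline value: it ignores the few
# neighborhoods distorted by noise or boundary effects.
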