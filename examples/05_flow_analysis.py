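"""Flow analysis of a synthetic polarized-fluorescence movie.

Renders a nematic texture advected by a known multi-vortex flow, recovers
the velocity field with Horn-Schunck optical flow, and measures the flow
observables — mean/RMS speed, the 1/e velocity autocorrelation length,
and the vortex length scale ell_vort — against the generator's ground
truth (vortex core radius 10 px).
"""

from actonem import (
    make_nematic_movie,
    make_vortex_field,
    mean_and_rms_speed,
    optical_flow_movie,
    summarize_flow,
)

truth = make_vortex_field(shape=(192, 192), n_vortices=8, core_radius=10.0,
                          peak_speed=1.5, seed=4)
frames, _ = make_nematic_movie(n_frames=8, shape=(192, 192), flow=truth, seed=2)

fields = optical_flow_movie(frames, pixel_size=1.0, dt=2.0)
summary = summarize_flow(fields)
true_mean, _ = mean_and_rms_speed(truth)

print(f"mean speed: estimated {summary.mean_speed:.3f} vs true {true_mean:.3f} µm/s")
print(f"rms speed:  {summary.rms_speed:.3f} µm/s")
print(f"velocity autocorrelation length: {summary.ell_corr:.1f} µm")
print(f"ell_vort: {summary.ell_vort:.1f} µm (ground-truth core radius 10, "
      "expected ~12% high from the correlation-kernel bias)")
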