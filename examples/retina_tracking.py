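"""Retina-driven visual tracking of a green circle on a red screen.

Two trials. First, the eye is held still while the target moves
sinusoidally: the red-green opponent retina plus the 1,280-neuron
two-layer readout decode the target's horizontal position, and we report
the Pearson correlation between the decoded and true pixel trajectories.
Second, a step trial: the target sits off-center and the decoded centroid
drives the eye's pan joint with a proportional controller until the target
is captured.
"""

import numpy as np

from neuroloop.experiments import run_retina_tracking

fixed = run_retina_tracking("fixed_eye", duration_ms=10000.0, seed=1)
corr = fixed.decode_correlation(settle_ms=2000.0)
print("fixed-eye trial (sinusoidal target, eye still)")
print("  time_s  true_px  decoded_px")
for i in range(100, len(fixed.times_ms), 60):
    d = fixed.decoded_px[i]
    print(f"  {fixed.times_ms[i] / 1000:6.1f}  {fixed.target_px[i]:7.1f}"
          f"  {d:10.1f}" if np.isfinite(d) else "        (no detection)")
print(f"  decoded-vs-true correlation: {corr:.3f}")

step = run_retina_tracking("step", duration_ms=6000.0, seed=1)
err = step.final_bearing_error_deg(tail_ms=1000.0)
print("\nstep trial (static off-center target, eye free)")
print(f"  initial target bearing: {np.rad2deg(step.target_bearing[0]):.1f} deg")
print(f"  final bearing error:    {err:.2f} deg")
# Correlation near 1 means the spiking readout captures the target motion;
# a final bearing error under ~2 deg means the eye captured the target.
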