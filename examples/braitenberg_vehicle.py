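"""Braitenberg vehicle: search counterclockwise, then approach the red screen.

Runs the packaged 8-neuron closed loop and prints how the robot's distance
to the red screen and the two actor-neuron firing rates evolve. Early in
the run the robot sees no red, so the "go" channel dominates and one actor
fires alone (the robot spins in place); once red enters the image the two
actor rates converge and the robot drives at the screen.
"""

import numpy as np

from neuroloop.experiments import run_braitenberg
from neuroloop.experiments.braitenberg import RED_SCREEN_CENTER

result = run_braitenberg("red", seed=1)
distance = result.distance_to(RED_SCREEN_CENTER)

print("time_s  dist_m  red_left  red_right  rate_L_Hz  rate_R_Hz")
for i in range(0, len(distance), 62):
    t = result.times_ms[i] / 1000.0
    l, r = result.red_ratios[i]
    rl, rr = result.actor_rates[i]
    print(f"{t:6.1f}  {distance[i]:6.2f}  {l:8.2f}  {r:9.2f}"
          f"  {rl:9.1f}  {rr:9.1f}")

print(f"\nfinal distance to red screen: {distance[-1]:.3f} m")
print(f"total rotation while searching + homing: "
      f"{result.cumulative_rotation():.2f} rad")
# A final distance well under 0.5 m means the vehicle found and reached the
# red stimulus; equal actor rates at the end mean it was driving straight.
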