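"""Generate a synthetic driving session and inspect its behaviour.

Builds the default 652-second virtual-driving session: a Markov
key-press policy steers a vehicle that accelerates at 10 units/s^2 while
the forward key is held, coasts down by friction otherwise, and tips
over (speed reset) when turning above 35 units/s.  The matching sEEG has
14 hippocampal channels whose theta/gamma amplitude grows with speed.
"""

import numpy as np

from hipponav import SimConfig, generate_session

config = SimConfig(seed=1)
session, trace = generate_session(config)

print(f"behaviour: {len(trace.t)} samples at {config.behavior_dt} s steps, "
      f"{len(trace.events)} key/tip events")
print(f"sEEG:      {session.n_channels} channels x {session.n_samples} "
      f"samples at {session.fs:g} Hz")

edges = np.arange(0.0, 60.0, 10.0)
occupancy = np.histogram(trace.speed, bins=edges)[0] / len(trace.speed)
print("\nspeed-bin occupancy (fraction of session time):")
for k, frac in enumerate(occupancy):
    print(f"  [{edges[k]:2.0f}, {edges[k + 1]:2.0f}) units/s : {frac:.3f}")
n_tips = sum(1 for _, tag in trace.events if tag == "tip_over")
print(f"\ntip-overs: {n_tips} — each resets speed to 0 for "
      f"{config.tip_delay_s:g} s, pushing time into the slowest bin")
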