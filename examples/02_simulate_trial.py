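"""Simulate one 2-minute stance trial of the Independent Channel model.

The body is an inverted pendulum stabilised by a delayed PD controller
acting on weighted sensory feedback plus low-pass positive force feedback;
a pink torque disturbance plays the role of sensory/motor noise.  Seven
perturbation periods are integrated and the first is discarded as transient.
"""

import numpy as np

import icposture as ip

anthro = ip.winter_anthropometry(77.7, 1.79)   # study-mean participant
params = ip.default_parameters(anthro)[ip.Condition(1.0, "closed")]

states = ip.generate_prts_states(4)
pert = ip.prts_to_rotation(states, amplitude_pp=1.0, fs=1000.0)
trial = ip.simulate_closed_loop(params, pert, ip.NoiseConfig(seed=1),
                                n_periods_total=6)

print(f"pendulum: m={anthro.m:.1f} kg, h={anthro.h:.3f} m, J={anthro.J:.1f} kg m^2, "
      f"m*g*h={anthro.mgh:.0f} N m/rad")
print(f"condition        : {trial.condition.label}")
print(f"trial duration   : {trial.duration:.0f} s ({trial.n_periods} periods)")
print(f"SS rotation RMS  : {trial.ss.y.std():.3f} deg")
print(f"body sway RMS    : {trial.bs.y.std():.3f} deg")
print(f"body sway range  : [{trial.bs.y.min():.3f}, {trial.bs.y.max():.3f}] deg")
print("\nSway stays within a fraction of a degree: the loop is stable and the")
print("noise adds a realistic non-periodic component on top of the evoked sway.")
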