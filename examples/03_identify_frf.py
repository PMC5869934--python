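"""Identify the frequency response function and coherence of a trial.

The trial is cut into six 20 s blocks (one perturbation period each); the
FRF is the cross-spectrum of perturbation and sway over the perturbation
power spectrum, formed from block-averaged Fourier coefficients, and the
coherence measures the linearly perturbation-evoked share of sway power.
"""

import numpy as np

import icposture as ip

anthro = ip.winter_anthropometry(77.7, 1.79)
params = ip.default_parameters(anthro)[ip.Condition(1.0, "closed")]
pert = ip.prts_to_rotation(ip.generate_prts_states(4), amplitude_pp=1.0, fs=1000.0)
trial = ip.simulate_closed_loop(params, pert, ip.NoiseConfig(seed=1), n_periods_total=6)

spec = ip.estimate_frf(trial.ss, trial.bs, period=20.0, n_blocks=6, f_max=2.05)

print(f"{'f (Hz)':>7} {'|H|':>7} {'phase (deg)':>12} {'coherence':>10}")
for i in range(0, len(spec.freqs), 4):
    print(f"{spec.freqs[i]:>7.2f} {np.abs(spec.frf[i]):>7.3f} "
          f"{np.degrees(np.angle(spec.frf[i])):>12.1f} {spec.coherence[i]:>10.3f}")
print(f"\neven-harmonic sway power : {spec.even_fraction:.2f} %")
print("\n|H| near 1 at low frequency (sway follows the platform), growing phase")
print("lag with frequency (the lumped delay), and coherence below 1 where the")
print("pink noise competes with the evoked response.  The low even-harmonic")
print("share confirms an essentially linear response.")
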