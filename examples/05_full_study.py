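"""Run the full four-condition study: simulate, identify, fit, compare.

Two perturbation amplitudes (0.5 and 1 degree peak-to-peak) crossed with
eyes open/closed; each condition is simulated with the common pink-noise
amplitude, identified, fitted, and scored with the time-domain VAF (sway
predicted by the fitted parameters vs the noisy observation) and the mean
relative parameter difference against the ground truth.
"""

import icposture as ip

cfg = ip.default_study_config(seed=1)
report = ip.run_study(cfg)

print(f"{'condition':>14} {'W_p true':>9} {'W_p est':>8} {'K_P/mgh':>8} "
      f"{'relDiff%':>9} {'VAF%':>6}")
for entry in report.to_dict()["conditions"]:
    t, h = entry["params_true"], entry["params_hat"]
    kp_n = h["K_P"] / (h["m"] * h["g"] * h["h"])
    print(f"{entry['condition']:>14} {t['W_p']:>9.3f} {h['W_p']:>8.3f} {kp_n:>8.3f} "
          f"{entry['rel_mean_diff_percent']:>9.1f} {entry['vaf_between_percent']:>6.1f}")

print("\nThe proprioceptive weight drops with amplitude and with the eyes open")
print("(sensory reweighting), the VAF rises with amplitude (better SNR at a")
print("constant noise level), and the mean parameter difference is dominated")
print("by the weakly identified force-feedback pair.")
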