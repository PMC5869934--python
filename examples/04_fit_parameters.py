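"""Fit the IC model to an identified FRF and inspect the estimates.

The coherence/frequency-weighted log-ratio error between the identified and
the model FRF is minimised over (W_p, K_P, K_D, tau_D, tau_F, K_F) with
anthropometry fixed; standard errors come from the curvature of the error at
the optimum.
"""

import icposture as ip

anthro = ip.winter_anthropometry(77.7, 1.79)
cond = ip.Condition(1.0, "closed")
truth = ip.default_parameters(anthro)[cond]
pert = ip.prts_to_rotation(ip.generate_prts_states(4), amplitude_pp=1.0, fs=1000.0)
trial = ip.simulate_closed_loop(truth, pert, ip.NoiseConfig(seed=1), n_periods_total=6)
spec = ip.estimate_frf(trial.ss, trial.bs, period=20.0, n_blocks=6)

res = ip.fit_ic_model(spec, anthro, cond)

print(f"{'parameter':>9} {'true':>10} {'estimate':>10} {'SEM':>10}")
for k in ip.FREE_PARAMETERS:
    print(f"{k:>9} {getattr(truth, k):>10.4g} {getattr(res.params_hat, k):>10.4g} "
          f"{res.sem[k]:>10.3g}")
kp_n, kd_n = ip.normalized_gains(res.params_hat)
print(f"\ncost E                   : {res.cost_E:.3e}")
print(f"normalised stiffness     : {kp_n:.3f} (K_P / mgh)")
print(f"normalised damping       : {kd_n:.3f} (K_D / mgh)")
print(f"resolved weights         : {res.weights_resolved}")
if res.warnings:
    print(f"warnings                 : {res.warnings}")
print("\nW_p, the PD gains and the delay are recovered to a few percent; the")
print("force-feedback pair (tau_F, K_F) acts below the lowest excited frequency")
print("and is weakly identified — its large SEM flags exactly that.")
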