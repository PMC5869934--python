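"""Closed-loop simulator: pink noise, oracle equivalence, delay realisation."""

import numpy as np
import pytest
from scipy import signal as sps

import icposture as ip
from icposture.prts import PerturbationSignal
from icposture.simulate import _subseed


def zero_perturbation(n_samples=20000, fs=1000.0):
    return PerturbationSignal(
        states=np.zeros(80, dtype=int), dt_state=0.25,
        velocity=np.zeros(n_samples), position=np.zeros(n_samples),
        fs=fs, period=n_samples / fs, amplitude_pp=0.0)


class TestPinkNoise:
    def test_zero_amplitude_gives_zeros(self):
        y = ip.pink_noise(1000, 100.0, ip.NoiseConfig(amplitude=0.0, seed=1))
        assert np.all(y == 0)

    def test_rms_matches_amplitude(self):
        y = ip.pink_noise(100000, 1000.0, ip.NoiseConfig(amplitude=2.5, seed=3))
        assert np.sqrt(np.mean(y**2)) == pytest.approx(2.5, rel=1e-9)
        assert np.mean(y) == pytest.approx(0.0, abs=1e-9)

    def test_loglog_psd_slope_is_minus_one(self):
        y = ip.pink_noise(10**6, 1000.0, ip.NoiseConfig(amplitude=1.0, seed=5))
        f, p = sps.welch(y, fs=1000.0, nperseg=2**15)
        band = (f >= 0.05) & (f <= 2.0)
        slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_seed_determinism_and_independence(self):
        cfg = ip.NoiseConfig(amplitude=1.0, seed=11)
        y1 = ip.pink_noise(10000, 100.0, cfg)
        y2 = ip.pink_noise(10000, 100.0, cfg)
        y3 = ip.pink_noise(10000, 100.0, ip.NoiseConfig(amplitude=1.0, seed=12))
        np.testing.assert_array_equal(y1, y2)
        assert abs(np.corrcoef(y1, y3)[0, 1]) < 0.1


class TestClosedLoop:
    def test_equilibrium_without_input(self, params_ec):
        trial = ip.simulate_closed_loop(
            params_ec, zero_perturbation(), ip.NoiseConfig(amplitude=0.0),
            n_periods_total=2, condition=ip.Condition(1.0, "closed"))
        assert np.all(trial.bs.y == 0)

    def test_noise_free_frf_matches_analytic_sensitivity(self, params_ec, noise_free_trial):
        """Time-domain route vs the frequency-domain closed form: within 1%
        magnitude and 1 degree phase at all 21 excited harmonics."""
        spec = ip.estimate_frf(noise_free_trial.ss, noise_free_trial.bs,
                               period=20.0, n_blocks=6)
        H_an = ip.closed_loop_sensitivity(params_ec, spec.freqs)
        mag_err = np.abs(np.abs(spec.frf) / np.abs(H_an) - 1.0)
        phase_err_deg = np.degrees(np.abs(np.angle(spec.frf / H_an)))
        assert mag_err.max() < 0.01
        assert phase_err_deg.max() < 1.0

    def test_steady_state_coherence_is_unity_without_noise(self, params_ec, perturbation):
        trial = ip.simulate_closed_loop(
            params_ec, perturbation, ip.NoiseConfig(amplitude=0.0),
            n_periods_total=6, n_transient_periods=3)
        coh = ip.coherence(trial.ss, trial.bs, period=20.0, n_blocks=6)
        assert np.all(coh > 1.0 - 1e-6)

    def test_noise_drops_coherence_below_one(self, noisy_trial):
        coh = ip.coherence(noisy_trial.ss, noisy_trial.bs, period=20.0, n_blocks=6)
        assert coh.min() < 1.0 - 1e-3
        assert np.all(coh <= 1.0 + 1e-12)

    def test_superposition_of_noise_and_perturbation(self, params_ec, perturbation):
        """The loop is linear: response to (perturbation + noise) minus the
        noise-only response equals the perturbation-only response."""
        noise = ip.NoiseConfig(amplitude=0.5, seed=9)
        both = ip.simulate_closed_loop(params_ec, perturbation, noise, n_periods_total=3)
        pert_only = ip.simulate_closed_loop(params_ec, perturbation,
                                            ip.NoiseConfig(amplitude=0.0), n_periods_total=3)
        zero = zero_perturbation()
        noise_only = ip.simulate_closed_loop(params_ec, zero, noise, n_periods_total=3,
                                             condition=both.condition)
        np.testing.assert_allclose(both.bs.y - noise_only.bs.y, pert_only.bs.y,
                                   atol=1e-8)

    def test_linearity_in_perturbation_amplitude(self, params_ec, prts_states):
        p1 = ip.prts_to_rotation(prts_states, amplitude_pp=0.5, fs=1000)
        p2 = ip.prts_to_rotation(prts_states, amplitude_pp=1.0, fs=1000)
        t1 = ip.simulate_closed_loop(params_ec, p1, ip.NoiseConfig(amplitude=0.0),
                                     n_periods_total=2)
        t2 = ip.simulate_closed_loop(params_ec, p2, ip.NoiseConfig(amplitude=0.0),
                                     n_periods_total=2)
        np.testing.assert_allclose(t2.bs.y, 2 * t1.bs.y, atol=1e-10)

    def test_delay_recovered_from_torque_residual(self, anthro, perturbation):
        """The torque is the delayed PD of the error: regressing T on the
        lagged (e, ė) pair recovers the configured lumped delay exactly."""
        p = ip.ICParameters.from_proprioceptive_weight(
            anthro, 0.55, "closed", K_P=1.6 * anthro.mgh, K_D=0.38 * anthro.mgh,
            tau_D=0.18, tau_F=20.0, K_F=0.0)   # K_F = 0 so e = Wp·SS - BS exactly
        trial = ip.simulate_closed_loop(
            p, perturbation, ip.NoiseConfig(amplitude=0.0),
            n_periods_total=3, keep_torque=True)
        fs = 1000.0
        e = p.W_p * np.radians(trial.ss.y) - np.radians(trial.bs.y)
        edot = np.gradient(e, 1.0 / fs)
        T = trial.torque.y
        sl = slice(500, len(T) - 500)
        resid = []
        lags = np.arange(100, 260)
        for lag in lags:
            pred = p.K_P * e[sl.start - lag:sl.stop - lag] + \
                p.K_D * edot[sl.start - lag:sl.stop - lag]
            resid.append(np.mean((T[sl] - pred) ** 2))
        d_hat = lags[int(np.argmin(resid))]
        assert abs(d_hat - round(p.tau_D * fs)) <= 1

    def test_unstable_parameters_rejected_before_integration(self, anthro):
        p = ip.ICParameters.from_proprioceptive_weight(
            anthro, 0.5, "closed", K_P=1.05 * anthro.mgh, K_D=0.0,
            tau_D=0.3, tau_F=10.0, K_F=0.0)
        with pytest.raises(ip.StabilityError):
            ip.check_stability(p)

    def test_fall_reports_divergence_time(self, anthro, perturbation):
        # marginally damped set that passes the Padé check but falls under
        # a huge disturbance
        p = ip.ICParameters.from_proprioceptive_weight(
            anthro, 0.5, "closed", K_P=1.5 * anthro.mgh, K_D=0.3 * anthro.mgh,
            tau_D=0.1, tau_F=10.0, K_F=0.0)
        with pytest.raises(ip.FallError) as err:
            ip.simulate_closed_loop(p, perturbation,
                                    ip.NoiseConfig(amplitude=5000.0, seed=1),
                                    n_periods_total=2)
        assert err.value.t_fall > 0

    def test_study_conditions_complete_without_fall(self, anthro):
        params = ip.default_parameters(anthro)
        trials = ip.generate_study_dataset(params, ip.NoiseConfig(seed=2), fs=500.0)
        assert len(trials) == 4
        for t in trials:
            assert t.duration == pytest.approx(120.0)


class TestStudyDataset:
    def test_missing_condition_rejected(self, anthro):
        params = ip.default_parameters(anthro)
        del params[ip.Condition(1.0, "closed")]
        with pytest.raises(ValueError, match="missing"):
            ip.generate_study_dataset(params, ip.NoiseConfig(seed=0))

    def test_eyes_closed_requires_no_visual_weight(self, anthro):
        params = ip.default_parameters(anthro)
        cond = ip.Condition(0.5, "closed")
        bad = params[cond]
        params[cond] = bad.replace(W_vis=0.1, W_ves=bad.W_ves - 0.1)
        with pytest.raises(ValueError, match="W_vis"):
            ip.generate_study_dataset(params, ip.NoiseConfig(seed=0))

    def test_subseeds_are_distinct_and_bounded(self):
        seeds = [_subseed(123, k) for k in range(4)]
        assert len(set(seeds)) == 4
        assert all(0 <= s < 2**31 for s in seeds)
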