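"""Weighted log-ratio cost, VAF, SEM and IC parameter estimation."""

import numpy as np
import pytest

import icposture as ip
from icposture.simulate import TimeSeries
from icposture.sysid import SpectralEstimate
from conftest import physiological_draw, relative_error_percent


def analytic_spectrum(params, freqs=None, coherence=None):
    freqs = ip.excited_frequencies() if freqs is None else freqs
    H = ip.closed_loop_sensitivity(params, freqs)
    coh = np.ones_like(freqs) if coherence is None else coherence
    return SpectralEstimate(freqs=freqs, frf=H, coherence=coh, csd=H,
                            psd_ss=np.ones_like(freqs), psd_bs=np.abs(H) ** 2,
                            n_blocks=6, even_fraction=0.0)


def make_ts(y, fs=100.0):
    y = np.asarray(y, dtype=float)
    return TimeSeries(t=np.arange(len(y)) / fs, y=y, fs=fs)


class TestPredictionError:
    def test_perfect_model_gives_zero(self, params_ec):
        freqs = ip.excited_frequencies()
        H = ip.closed_loop_sensitivity(params_ec, freqs)
        eps = ip.prediction_error(H, np.ones_like(freqs), params_ec, freqs)
        np.testing.assert_allclose(eps, 0.0, atol=1e-14)

    def test_magnitude_ratio_maps_to_log(self, params_ec):
        """Data twice the model at near-zero frequency with unit coherence:
        the weight tends to 1 and the error to ln 2."""
        freqs = np.array([1e-9])
        H = ip.closed_loop_sensitivity(params_ec, freqs)
        eps = ip.prediction_error(2 * H, np.array([1.0]), params_ec, freqs)
        assert eps[0] == pytest.approx(np.log(2.0), rel=1e-6)

    def test_pure_phase_mismatch(self, params_ec):
        """90 deg phase error at 1 Hz, unit coherence: weight 1/2, error
        (1/2)(π/2)."""
        freqs = np.array([1.0])
        H = ip.closed_loop_sensitivity(params_ec, freqs)
        eps = ip.prediction_error(H * np.exp(1j * np.pi / 2), np.array([1.0]),
                                  params_ec, freqs)
        assert eps[0] == pytest.approx(0.5 * np.pi / 2, rel=1e-12)

    def test_zero_frf_rejected(self, params_ec):
        freqs = np.array([0.05])
        with pytest.raises(ZeroDivisionError):
            ip.prediction_error(np.array([0.0 + 0j]), np.array([1.0]), params_ec, freqs)


class TestCost:
    def test_zero_vector(self):
        assert ip.cost(np.zeros(4)) == 0.0

    def test_unit_errors(self):
        assert ip.cost(np.ones(4)) == 1.0

    def test_mean_of_squares(self):
        assert ip.cost(np.array([3.0, 4.0])) == pytest.approx(12.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ip.cost(np.array([]))


class TestVAF:
    def test_identical_series_is_hundred(self):
        y = np.sin(np.linspace(0, 10, 500))
        assert ip.vaf(make_ts(y), make_ts(y)) == 100.0

    def test_zero_reference_constant_prediction(self):
        assert ip.vaf(make_ts(np.zeros(100)), make_ts(np.full(100, 2.0))) == pytest.approx(0.0)

    def test_constant_double_prediction(self):
        # reference c, prediction 2c: 1 - c^2/(4 c^2) = 75%
        assert ip.vaf(make_ts(np.full(50, 1.5)), make_ts(np.full(50, 3.0))) == pytest.approx(75.0)

    def test_zero_prediction_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ip.vaf(make_ts(np.ones(10)), make_ts(np.zeros(10)))


class TestSEM:
    def test_orthonormal_jacobian(self):
        J = np.eye(5)
        np.testing.assert_allclose(ip.sem(J, 4.0), 2.0)

    def test_column_scaling(self):
        rng = np.random.default_rng(0)
        J = rng.standard_normal((30, 3))
        s1 = ip.sem(J, 1.7)
        J2 = J.copy()
        J2[:, 1] *= 10.0
        s2 = ip.sem(J2, 1.7)
        assert s2[1] == pytest.approx(s1[1] / 10.0, rel=1e-9)

    def test_zero_cost_gives_zero_sem(self):
        J = np.eye(3)
        np.testing.assert_allclose(ip.sem(J, 0.0), 0.0)

    def test_singular_jacobian_rejected(self):
        J = np.zeros((10, 2))
        J[:, 0] = 1.0           # second column identically zero
        with pytest.raises(np.linalg.LinAlgError, match="identifiable"):
            ip.sem(J, 1.0)


class TestDeriveWeights:
    def test_eyes_closed_complement(self):
        w = ip.derive_weights(0.3, ip.Condition(1.0, "closed"))
        assert w == {"W_vis": 0.0, "W_ves": pytest.approx(0.7)}

    def test_full_proprioceptive(self):
        w = ip.derive_weights(1.0, ip.Condition(0.5, "closed"))
        assert w == {"W_vis": 0.0, "W_ves": pytest.approx(0.0)}

    def test_eyes_open_reports_combined_weight(self):
        w = ip.derive_weights(0.3, ip.Condition(1.0, "open"))
        assert w == {"W_vis_plus_ves": pytest.approx(0.7)}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ip.derive_weights(1.2, ip.Condition(1.0, "open"))


class TestCompareParameters:
    def test_identical_sets(self, params_ec):
        assert ip.compare_parameters(params_ec, params_ec) == 0.0

    def test_uniform_scaling(self, params_ec):
        a = params_ec.replace(
            K_P=1.1 * params_ec.K_P, K_D=1.1 * params_ec.K_D,
            W_p=1.1 * params_ec.W_p, W_ves=1 - 1.1 * params_ec.W_p,
            tau_D=1.1 * params_ec.tau_D, tau_F=1.1 * params_ec.tau_F,
            K_F=1.1 * params_ec.K_F)
        assert ip.compare_parameters(a, params_ec) == pytest.approx(10.0, rel=1e-9)

    def test_asymmetric_and_nonnegative(self, anthro):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = physiological_draw(rng, anthro)
            b = physiological_draw(rng, anthro)
            dab = ip.compare_parameters(a, b)
            dba = ip.compare_parameters(b, a)
            assert dab >= 0 and dba >= 0
            if a != b:
                assert dab != pytest.approx(dba, rel=1e-6)


class TestFitICModel:
    def test_self_consistency_on_analytic_frf(self, anthro, params_ec):
        """Fitting the closed-form FRF with no noise recovers every free
        parameter to well under 1%."""
        res = ip.fit_ic_model(analytic_spectrum(params_ec), anthro,
                              ip.Condition(1.0, "closed"))
        errs = relative_error_percent(res.params_hat, params_ec, ip.FREE_PARAMETERS)
        assert max(errs.values()) < 1.0
        assert res.converged

    def test_cost_at_optimum_not_worse_than_any_start(self, anthro, params_ec):
        from icposture.fit import _residual, _start_grid, FREE_PARAMETERS
        spec = analytic_spectrum(params_ec)
        res = ip.fit_ic_model(spec, anthro, ip.Condition(1.0, "closed"))
        w = spec.coherence / (1 + spec.freqs)
        for x0 in _start_grid(anthro, None):
            E0 = np.mean(_residual(x0, anthro, spec.freqs, spec.frf, w) ** 2)
            assert res.cost_E <= E0 + 1e-15

    def test_weight_bookkeeping(self, anthro, params_ec):
        for eyes in ("open", "closed"):
            res = ip.fit_ic_model(analytic_spectrum(params_ec), anthro,
                                  ip.Condition(1.0, eyes))
            p = res.params_hat
            assert p.W_p + p.W_vis + p.W_ves == pytest.approx(1.0, abs=1e-12)
            assert p.W_vis == 0.0

    def test_amplitude_invariance_noise_free(self, params_ec, prts_states, anthro):
        """The identified-then-fitted parameters do not depend on the
        perturbation amplitude in the noise-free (linear) case."""
        results = []
        for amp in (0.5, 1.0):
            pert = ip.prts_to_rotation(prts_states, amplitude_pp=amp, fs=500)
            tr = ip.simulate_closed_loop(params_ec, pert, ip.NoiseConfig(amplitude=0.0),
                                         n_periods_total=6)
            spec = ip.estimate_frf(tr.ss, tr.bs, period=20.0, n_blocks=6)
            results.append(ip.fit_ic_model(spec, anthro, ip.Condition(amp, "closed")))
        a, b = (r.params_hat for r in results)
        for k in ip.FREE_PARAMETERS:
            assert getattr(a, k) == pytest.approx(getattr(b, k), rel=1e-4)

    def test_noise_inflation_degrades_weight_recovery(self, params_ec, perturbation, anthro):
        """Median |W_p error| over seeds does not decrease when the noise
        amplitude is inflated."""
        cond = ip.Condition(1.0, "closed")
        med = []
        for amp in (0.25, 2.0):
            errs = []
            for seed in range(6):
                tr = ip.simulate_closed_loop(params_ec, perturbation,
                                             ip.NoiseConfig(amplitude=amp, seed=seed),
                                             n_periods_total=6)
                spec = ip.estimate_frf(tr.ss, tr.bs, period=20.0, n_blocks=6)
                res = ip.fit_ic_model(spec, anthro, cond)
                errs.append(abs(res.params_hat.W_p - params_ec.W_p))
            med.append(np.median(errs))
        assert med[1] >= med[0]

    def test_noisy_fit_flags_force_feedback_uncertainty(self, noisy_trial, anthro):
        """With study-like noise the force-feedback parameters carry much
        larger relative SEM than the well-identified four."""
        spec = ip.estimate_frf(noisy_trial.ss, noisy_trial.bs, period=20.0, n_blocks=6)
        res = ip.fit_ic_model(spec, anthro, ip.Condition(1.0, "closed"))
        p = res.params_hat
        rel_sem = {k: res.sem[k] / abs(getattr(p, k)) for k in ip.FREE_PARAMETERS
                   if np.isfinite(res.sem[k]) and getattr(p, k) != 0}
        core = [rel_sem[k] for k in ("W_p", "tau_D") if k in rel_sem]
        ff = [rel_sem[k] for k in ("tau_F", "K_F") if k in rel_sem]
        assert ff and core
        assert min(ff) > max(core)
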