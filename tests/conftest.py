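import numpy as np
import pytest

import icposture as ip


@pytest.fixture(scope="session")
def anthro():
    """Pendulum constants for the mean participant (77.7 kg, 1.79 m)."""
    return ip.winter_anthropometry(77.7, 1.79)


@pytest.fixture(scope="session")
def params_ec(anthro):
    """A typical eyes-closed parameter set."""
    return ip.ICParameters.from_proprioceptive_weight(
        anthro, 0.55, "closed",
        K_P=1.6 * anthro.mgh, K_D=0.38 * anthro.mgh,
        tau_D=0.18, tau_F=20.0, K_F=8e-4,
    )


@pytest.fixture(scope="session")
def prts_states():
    return ip.generate_prts_states(n_stages=4)


@pytest.fixture(scope="session")
def perturbation(prts_states):
    """1 deg peak-to-peak PRTS rotation at 1 kHz."""
    return ip.prts_to_rotation(prts_states, dt_state=0.25, amplitude_pp=1.0, fs=1000.0)


@pytest.fixture(scope="session")
def noise_free_trial(params_ec, perturbation):
    """Noise-free 6-period trial with the study's 1-period transient discard."""
    return ip.simulate_closed_loop(
        params_ec, perturbation, ip.NoiseConfig(amplitude=0.0), n_periods_total=6)


@pytest.fixture(scope="session")
def noisy_trial(params_ec, perturbation):
    """Six-period trial with the default pink torque noise."""
    return ip.simulate_closed_loop(
        params_ec, perturbation, ip.NoiseConfig(seed=42), n_periods_total=6)


def physiological_draw(rng, anthro):
    """One random stable parameter set from the physiological ranges."""
    while True:
        p = ip.ICParameters.from_proprioceptive_weight(
            anthro, rng.uniform(0.3, 0.8), "closed",
            K_P=rng.uniform(1.2, 2.5) * anthro.mgh,
            K_D=rng.uniform(0.25, 0.6) * anthro.mgh,
            tau_D=round(rng.uniform(0.08, 0.24), 3),
            tau_F=rng.uniform(5.0, 40.0),
            K_F=rng.uniform(2e-4, 2e-3),
        )
        try:
            ip.check_stability(p)
            return p
        except ip.StabilityError:
            continue


def relative_error_percent(estimate, truth, names):
    return {k: 100.0 * abs(getattr(estimate, k) - getattr(truth, k)) / abs(getattr(truth, k))
            for k in names}
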