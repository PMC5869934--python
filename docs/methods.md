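# Methods

## Model and assumptions

The stance model is the Independent Channel structure: a single inverted
pendulum pivoting about the ankle axis, linearised about upright
(J·θ̈ = m·g·h·θ + T), controlled by a PD neural controller through a lumped
delay acting on a weighted sum of sensory error signals plus a first-order
low-pass positive torque feedback. The linearisation restricts validity to
small sway about a fixed operating point; hip strategy, muscle/activation
dynamics and intrinsic ankle stiffness are outside the model. With an
earth-fixed visual surround the visual and vestibular channels carry the
same body-in-space signal, so the loop dynamics depend only on the
proprioceptive weight W_p and the complementary space-referenced weight
1 − W_p; the visual/vestibular split is bookkeeping. Eyes closed forces
W_vis = 0 so W_ves = 1 − W_p; eyes open only the combined weight 1 − W_p is
reported (the split is not identifiable from platform rotations).

Internally everything is SI (radians, N·m); degrees appear only at I/O
boundaries, because perturbation amplitudes and sway are conventionally
printed in degrees.

## Parameters

| symbol | meaning | unit | default (EC, 1°) |
|---|---|---|---|
| m, h, J | pendulum mass / CoM height / inertia | kg, m, kg·m² | 75.4, 1.005, 87.8 (from 77.7 kg, 1.79 m) |
| W_p | proprioceptive weight | – | 0.55 |
| K_P | reflexive stiffness | N·m/rad | 1.60·mgh |
| K_D | reflexive damping | N·m·s/rad | 0.48·mgh |
| τ_D | lumped delay | s | 0.16 |
| τ_F | force-feedback time constant | s | 20 |
| K_F | force-feedback gain | rad/(N·m) | 8·10⁻⁴ |

K_P must exceed the gravitational stiffness m·g·h (closed-loop DC
stability); this is enforced by the parameter type. The per-condition
defaults encode the sensory-reweighting pattern (W_p drops with perturbation
amplitude and with the eyes open, stiffness rises with amplitude) and were
chosen inside field-typical physiological ranges with damping such that the
closed-loop FRF peaks at a realistic 1.5–3 around 0.3–0.5 Hz; a lightly
damped set with the same stiffness can peak far higher without being
unstable, which is not what stance FRFs look like.

Anthropometry is derived from total mass and stature with a frozen
Winter-style segment table (feet excluded; constants `WINTER_*` in
`model.py`). The exact fractions are one standard edition's values; any
consistent table would do, but freezing them makes every derived quantity
deterministic.

## Perturbation

The PRTS is generated by an n-stage linear feedback shift register over
GF(3) with frozen primitive taps (degree 4: (0,0,1,1), found by exhaustive
search and verified by walking all 3⁴ − 1 register states). Symbols
{0, 1, 2} map to velocities {0, +v, −v}; each state is held 0.25 s; the
cumulative integral is mean-removed and rescaled to the requested
peak-to-peak amplitude. Because the second half of a ternary m-sequence is
the negation of the first, the integrated position is anti-periodic over
half a period and carries power only on odd harmonics of 1/20 Hz — verified
in the tests at the 1e-10 level rather than against any particular published
waveform, since the feedback polynomial in use elsewhere is not published.

## Simulation

The closed loop is integrated with fixed-step classical Runge–Kutta at the
sample rate (default 1000 Hz; 100 Hz-style rates are supported), with the
delay as a circular buffer of whole samples (τ_D·fs is snapped to the
nearest integer, with a warning when it is not one already). One detail
matters for accuracy: the delayed PD torque is split into an exogenous part
driven by the perturbation and an endogenous part driven by the body and
force-feedback states. The PRTS velocity is piecewise constant over whole
samples, so the exogenous part is evaluated exactly at the RK4 stage times;
interpolating it linearly instead smears its jumps and biases the simulated
FRF by a fraction of a sample (≈0.33° phase at 2.05 Hz at 1 kHz). With the
split, the noise-free simulated FRF matches the analytic closed-loop
sensitivity to ≤5·10⁻⁵ relative magnitude and ≤0.002° phase at 1 kHz.

Noise is a single additive pink (1/f over the analysis band) torque
disturbance at the plant input, RMS-scaled, shaped in the frequency domain
and reproducible from a seed. A torque-equivalent disturbance leaves the
SS→BS transfer unchanged in expectation, which is what the spectral
estimators assume. Its default RMS of 0.5 N·m puts a 1° eyes-closed trial
in the good-signal-to-noise regime of a model simulation — coherence close
to, but visibly below, one (mean ≈0.95, minimum ≈0.8 across the excited
band) — clearly above typical human coherence, which is additionally
degraded by physiological variability the generator does not emulate.

Trials simulate n_transient + 6 periods and analyse the last six; the
default single discarded period mirrors the short familiarisation given to
human participants. Note that with τ_F of tens of seconds the
force-feedback state settles slowly: steady-state properties (coherence
exactly 1 without noise; recovery of τ_F/K_F to fractions of a percent)
require 3–8 discarded periods, and the tests that assert those properties
discard that many. A fall guard aborts integration when |sway| exceeds
0.5 rad, and a Padé(2,2) root check rejects unstable parameter sets before
integrating.

What the generator does not emulate: multi-segment (hip) kinematics,
sensory-channel-specific noise (available as the torque-equivalent lump
only), nonlinear large-angle dynamics, trial-to-trial parameter drift, and
measurement noise of the motion capture. Passing recovery tests therefore
demonstrate correctness of the estimation chain under the model's own
assumptions, not robustness to the ways real data violate them.

## Identification

Trials are segmented into exact perturbation periods; no window is applied
because the blocks are integer periods of a periodic excitation (zero
leakage at the harmonics by construction). The FRF uses spectra formed from
block-averaged Fourier coefficients (the periodic part of the response).
The coherence cannot use fully averaged coefficients — that estimator is
identically one — so it uses the standard form: per-block cross products
averaged across blocks over block-averaged powers. With L independent
blocks its bias under independence is ≈1/L (checked by Monte Carlo at
L = 6). Frequencies where the sway has no power give an undefined, not
zero, coherence. DC and frequencies above the band edge (default 2.05 Hz)
are excluded everywhere; the even-harmonic sway-power fraction is reported
as the nonlinearity screen.

## Fitting

The residual ε(f) = γ²(f)/(1+f)·|log(H_exp/H_est)| weights low frequencies
and high-coherence frequencies. The modulus has a derivative kink at a
perfect fit, so the optimizer minimises the stacked real/imaginary parts of
the weighted complex log-ratio — the identical sum of squares with a smooth
Jacobian — via `scipy.optimize.least_squares` (trust-region reflective)
under the physiological box bounds W_p ∈ [0,1], K_P ∈ (mgh, 10·mgh],
K_D ∈ [0, 5·mgh], τ_D ∈ [0.05, 0.4] s, τ_F ∈ [1, 100] s,
K_F ∈ [0, 0.01] rad/N·m, started from a deterministic 8-point grid
(W_p ∈ {0.3, 0.7} × K_P ∈ {1.5, 3}·mgh × τ_D ∈ {0.1, 0.2}). The complex log
uses the principal branch; estimates pinned at a bound are recorded as
warnings in the result.

SEM is the square root of the diagonal of E·(JᵀJ)⁻¹ with J the
central-finite-difference Jacobian (relative step 1e-6) of the modulus
residual at the optimum and E the normalised cost (1/N)·εᵀε; using the
unnormalised sum instead would scale all SEMs by √N, so SEM-based
conclusions are treated as order-of-magnitude. A singular JᵀJ is reported
as per-parameter non-identifiability rather than as numbers. The VAF uses
the predicted series in the denominator — unconventional but kept as the
definition this analysis chain is built around.

τ_F and K_F act mostly below the lowest excited frequency (0.05 Hz), so a
20 s perturbation period carries little information about them: with noise
their estimates scatter widely and their SEMs are orders of magnitude
larger than those of W_p, K_P, K_D and τ_D. This is expected behaviour, not
an estimator defect, and the tests assert the pattern rather than tight
bounds on those two parameters.

## Problem sizes and determinism

Default study runs are four 2-min trials at 1000 Hz; the test suite uses
200–1000 Hz and 6-period trials, with recovery studies over 20 random
ground-truth sets and Monte-Carlo estimator calibrations over 300–1000
seeds — sizes chosen so the whole suite runs in well under a minute after
JIT warm-up while keeping sampling error far below the asserted tolerances.
All randomness flows through explicit integer seeds; study runs derive
per-condition sub-seeds deterministically from the global seed, and a rerun
with the same seed reproduces the report byte for byte.

## Known limitations

- The eyes-open visual/vestibular split is not identifiable; the combined
  weight is reported.
- τ_F/K_F are weakly identifiable from 20 s-periodic perturbations (above).
- The delay must be an integer number of samples; fitted delays are snapped
  when re-simulated for prediction, which perturbs the predicted sway by at
  most half a sample of timing.
- The simulator is linear by construction; the even-harmonic screen on its
  output measures only noise leakage, not genuine nonlinearity.
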