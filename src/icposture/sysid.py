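"""Non-parametric closed-loop identification from periodic perturbation trials.

The trial is cut into blocks of exactly one perturbation period, each block
is Fourier-transformed, and spectra are formed at the harmonics of 1/period.
Because the blocks are exact periods of a periodic excitation, no window is
needed: leakage at the harmonics is zero by construction.

The FRF uses the *averaged* Fourier coefficients (the periodic part of the
response):

    H_exp(f) = Phi_SS,BS(f) / Phi_SS,SS(f),   Phi from block-mean coefficients

while the coherence uses per-block cross products and per-block powers
averaged across blocks — the standard magnitude-squared coherence estimator,
which drops below one with noise and nonlinearities (a literal
averaged-coefficient reading would give gamma^2 = 1 identically):

    gamma^2(f) = |<SS_b* BS_b>|^2 / (<|SS_b|^2> <|BS_b|^2>)

Only the excited odd harmonics up to f_max are analysed; the even harmonics
carry no perturbation power and their share of the sway power is the
nonlinearity screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TimeSeries

__all__ = [
    "SpectralEstimate",
    "segment_and_transform",
    "estimate_frf",
    "coherence",
    "even_harmonic_power_fraction",
]


@dataclass(frozen=True)
class SpectralEstimate:
    """Spectral quantities at the excited (odd-harmonic) frequencies."""

    freqs: np.ndarray          # Hz
    frf: np.ndarray            # complex H_exp(f)
    coherence: np.ndarray      # gamma^2 per frequency
    csd: np.ndarray            # Phi_SS,BS (block-averaged cross products)
    psd_ss: np.ndarray         # Phi_SS,SS (block-averaged power)
    psd_bs: np.ndarray         # Phi_BS,BS
    n_blocks: int
    even_fraction: float       # % of sway power on even harmonics <= f_max

    def __post_init__(self) -> None:
        n = len(self.freqs)
        for name in ("frf", "coherence", "csd", "psd_ss", "psd_bs"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match freqs")
        if np.any(self.coherence < -1e-12) or np.any(self.coherence > 1 + 1e-12):
            raise ValueError("coherence must lie in [0, 1]")


def _block_samples(ts: TimeSeries, period: float, n_blocks: int) -> int:
    nb = period * ts.fs
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError(f"period·fs = {nb} is not an integer number of samples")
    nb = int(round(nb))
    expected = n_blocks * nb
    if len(ts) != expected:
        raise ValueError(
            f"time series has {len(ts)} samples; expected n_blocks·period·fs = {expected}"
        )
    return nb


def segment_and_transform(ts: TimeSeries, period: float, n_blocks: int):
    """Per-block Fourier coefficients at the harmonics of 1/period.

    Returns ``(freqs, block_coeffs, mean_coeffs)`` where ``block_coeffs`` has
    shape (n_blocks, n_harmonics) and ``mean_coeffs`` is the across-block
    average — the periodic part of the response.  Coefficients are the
    complex amplitudes X_k = (1/N) sum x[n] exp(-2πi k n/N), so a cosine of
    amplitude A at harmonic k gives |X_k| = A/2.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    nb = _block_samples(ts, period, n_blocks)
    blocks = ts.y.reshape(n_blocks, nb)
    coeffs = np.fft.rfft(blocks, axis=1) / nb
    freqs = np.fft.rfftfreq(nb, d=1.0 / ts.fs)
    return freqs, coeffs, coeffs.mean(axis=0)


def _harmonic_indices(freqs: np.ndarray, period: float, f_max: float):
    """Indices of (odd, even) harmonics of 1/period with 0 < f <= f_max."""
    f0 = 1.0 / period
    k = np.rint(freqs / f0).astype(int)
    in_band = (k >= 1) & (freqs <= f_max + 1e-9)
    odd = np.where(in_band & (k % 2 == 1))[0]
    even = np.where(in_band & (k % 2 == 0))[0]
    return odd, even


def estimate_frf(ss: TimeSeries, bs: TimeSeries, period: float,
                 n_blocks: int = 6, f_max: float = 2.05) -> SpectralEstimate:
    """FRF, coherence and even-harmonic screen from an (SS, BS) trial.

    The FRF is the ratio of the cross-spectral density of perturbation and
    sway to the power spectral density of the perturbation, both formed from
    the block-averaged Fourier coefficients; evaluated at the excited odd
    harmonics up to ``f_max``.
    """
    if len(ss) != len(bs) or abs(ss.fs - bs.fs) > 1e-12:
        raise ValueError("ss and bs must share length and sample rate")
    freqs, ss_blocks, ss_mean = segment_and_transform(ss, period, n_blocks)
    _, bs_blocks, bs_mean = segment_and_transform(bs, period, n_blocks)
    odd, even = _harmonic_indices(freqs, period, f_max)

    psd_ss_mean = np.abs(ss_mean[odd]) ** 2
    zero = psd_ss_mean <= 1e-24 * psd_ss_mean.max() if psd_ss_mean.size else psd_ss_mean < 0
    if np.any(zero):
        raise ZeroDivisionError(
            f"perturbation has no power at excited frequency {freqs[odd][zero][0]:.6g} Hz"
        )
    csd_mean = np.conj(ss_mean[odd]) * bs_mean[odd]
    frf = csd_mean / psd_ss_mean

    # coherence: block cross products / block powers
    csd_blk = np.mean(np.conj(ss_blocks[:, odd]) * bs_blocks[:, odd], axis=0)
    psd_ss_blk = np.mean(np.abs(ss_blocks[:, odd]) ** 2, axis=0)
    psd_bs_blk = np.mean(np.abs(bs_blocks[:, odd]) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(csd_blk) ** 2 / (psd_ss_blk * psd_bs_blk)
    coh = np.where(psd_bs_blk > 0, coh, np.nan)
    coh = np.minimum(coh, 1.0 + 1e-15)

    # even-harmonic nonlinearity screen on the sway
    bs_power = np.mean(np.abs(bs_blocks) ** 2, axis=0)
    total = bs_power[odd].sum() + bs_power[even].sum()
    even_frac = 100.0 * bs_power[even].sum() / total if total > 0 else np.nan

    return SpectralEstimate(
        freqs=freqs[odd], frf=frf, coherence=coh,
        csd=csd_blk, psd_ss=psd_ss_blk, psd_bs=psd_bs_blk,
        n_blocks=n_blocks, even_fraction=float(even_frac),
    )


def coherence(ss: TimeSeries, bs: TimeSeries, period: float,
              n_blocks: int = 6, f_max: float = 2.05) -> np.ndarray:
    """Magnitude-squared coherence gamma^2 at the excited odd harmonics.

    Requires at least two blocks: with a single block the estimator is
    identically one and carries no information.  Frequencies where the sway
    has zero power are reported as NaN (undefined), never as zero.
    """
    if n_blocks < 2:
        raise ValueError("coherence needs n_blocks >= 2 to be non-degenerate")
    return estimate_frf(ss, bs, period, n_blocks, f_max).coherence


def even_harmonic_power_fraction(bs: TimeSeries, period: float,
                                 n_blocks: int = 6, f_max: float = 2.05) -> float:
    """Percentage of sway power on the unexcited even harmonics up to f_max.

    DC is excluded.  Power is the across-block mean of per-block power.  A
    low percentage justifies treating the response as linear.
    """
    freqs, blocks, _ = segment_and_transform(bs, period, n_blocks)
    odd, even = _harmonic_indices(freqs, period, f_max)
    power = np.mean(np.abs(blocks) ** 2, axis=0)
    total = power[odd].sum() + power[even].sum()
    if total <= 0:
        raise ValueError("signal has zero power on the analysed harmonics")
    return float(100.0 * power[even].sum() / total)
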