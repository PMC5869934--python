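"""Pseudorandom ternary sequence (PRTS) perturbations.

A maximal-length ternary sequence from an n-stage linear feedback shift
register over GF(3) has period 3^n - 1; with four stages and a 0.25 s state
duration one period is 80 states = 20 s.  The symbols {0, 1, 2} map to
angular velocities {0, +v, -v}; integrating the velocity gives the
support-surface rotation waveform.  Because the second half of a ternary
m-sequence period is the elementwise negation of the first half, the
integrated (mean-removed) position is anti-periodic over half a period and
therefore carries power only on the odd harmonics of 1/period — the even
harmonics stay clean and serve as a nonlinearity probe in the output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerturbationSignal",
    "generate_prts_states",
    "prts_period",
    "prts_to_rotation",
    "excited_frequencies",
    "PRIMITIVE_TAPS",
]

# Frozen feedback taps (c_1 .. c_n) of the GF(3) recursion
#   r_new = (c_1 r_1 + ... + c_n r_n) mod 3
# verified maximal (period 3^n - 1) by exhaustive register walk.
PRIMITIVE_TAPS: dict[int, tuple[int, ...]] = {
    2: (1, 1),
    3: (0, 1, 2),
    4: (0, 0, 1, 1),
    5: (0, 0, 0, 1, 2),
    6: (0, 0, 0, 0, 1, 1),
}


def _search_taps(n_stages: int) -> tuple[int, ...]:
    """Find maximal-length feedback taps by brute force (small n only)."""
    for taps in itertools.product(range(3), repeat=n_stages):
        if taps[-1] == 0:
            continue
        if prts_period(n_stages, taps=taps) == 3**n_stages - 1:
            return taps
    raise RuntimeError(f"no maximal-length taps found for {n_stages} stages")


def _taps_for(n_stages: int) -> tuple[int, ...]:
    if n_stages in PRIMITIVE_TAPS:
        return PRIMITIVE_TAPS[n_stages]
    return _search_taps(n_stages)


def prts_period(n_stages: int, taps: tuple[int, ...] | None = None,
                seed_state: tuple[int, ...] | None = None) -> int:
    """Measure the period of the shift-register sequence by walking the
    register until the initial state recurs."""
    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    taps = tuple(taps) if taps is not None else _taps_for(n_stages)
    state = tuple(seed_state) if seed_state is not None else (1,) + (0,) * (n_stages - 1)
    if all(v == 0 for v in state):
        raise ValueError("seed_state must not be all zero (degenerate register)")
    start = state
    for step in range(1, 3**n_stages + 1):
        fb = sum(c * s for c, s in zip(taps, state)) % 3
        state = (fb,) + state[:-1]
        if state == start:
            return step
    raise RuntimeError("register walk did not return to the seed state")


def generate_prts_states(n_stages: int = 4,
                         seed_state: tuple[int, ...] | None = None) -> np.ndarray:
    """One period of the maximal-length ternary sequence (symbols 0/1/2).

    The register emits its last stage each tick; for n_stages = 4 the period
    is 80 states.  All non-zero seed states produce cyclic shifts of the same
    sequence.
    """
    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    taps = _taps_for(n_stages)
    state = list(seed_state) if seed_state is not None else [1] + [0] * (n_stages - 1)
    if len(state) != n_stages:
        raise ValueError(f"seed_state must have {n_stages} entries")
    if all(v == 0 for v in state):
        raise ValueError("seed_state must not be all zero (degenerate register)")
    period = 3**n_stages - 1
    out = np.empty(period, dtype=np.int64)
    for k in range(period):
        out[k] = state[-1]
        fb = sum(c * s for c, s in zip(taps, state)) % 3
        state = [fb] + state[:-1]
    return out


# symbol -> velocity sign
_SYMBOL_TO_SIGN = np.array([0.0, 1.0, -1.0])


@dataclass(frozen=True)
class PerturbationSignal:
    """PRTS support-surface rotation over one period.

    ``velocity`` (deg/s) and ``position`` (deg) are sampled at ``fs``;
    position is mean-removed and scaled so its peak-to-peak span equals
    ``amplitude_pp`` degrees.
    """

    states: np.ndarray
    dt_state: float
    velocity: np.ndarray
    position: np.ndarray
    fs: float
    period: float
    amplitude_pp: float

    def __post_init__(self) -> None:
        if len(self.velocity) != len(self.position):
            raise ValueError("velocity and position must have equal length")
        if abs(len(self.states) * self.dt_state - self.period) > 1e-9:
            raise ValueError("len(states)·dt_state must equal period")
        pp = float(np.max(self.position) - np.min(self.position))
        if abs(pp - self.amplitude_pp) > 1e-9:
            raise ValueError(f"position peak-to-peak {pp} != amplitude_pp {self.amplitude_pp}")

    @property
    def n_samples(self) -> int:
        return len(self.position)

    def tile(self, n_periods: int) -> tuple[np.ndarray, np.ndarray]:
        """(position, velocity) tiled over n_periods, still at ``fs``."""
        return np.tile(self.position, n_periods), np.tile(self.velocity, n_periods)


def prts_to_rotation(states: np.ndarray, dt_state: float = 0.25,
                     amplitude_pp: float = 1.0, fs: float = 1000.0) -> PerturbationSignal:
    """Integrate a ternary symbol sequence into the SS rotation waveform.

    Symbols map to velocities {0 -> 0, 1 -> +v, 2 -> -v}, each held for
    ``dt_state``; the cumulative integral is mean-removed and rescaled so the
    position peak-to-peak equals ``amplitude_pp`` degrees.  ``fs * dt_state``
    must be an integer so every state spans a whole number of samples.
    """
    states = np.asarray(states, dtype=np.int64)
    if amplitude_pp <= 0:
        raise ValueError(f"amplitude_pp must be > 0, got {amplitude_pp}")
    sps = fs * dt_state
    if abs(sps - round(sps)) > 1e-9:
        raise ValueError(
            f"fs·dt_state = {sps} is not an integer; each state must span a whole number of samples"
        )
    sps = int(round(sps))
    vel = np.repeat(_SYMBOL_TO_SIGN[states], sps)
    # left Riemann sum: exact for a piecewise-constant velocity held over samples
    pos = np.concatenate(([0.0], np.cumsum(vel)[:-1])) / fs
    pos = pos - pos.mean()
    span = float(np.max(pos) - np.min(pos))
    if span == 0.0:
        scale = 0.0
        if np.any(states != 0):  # pragma: no cover - cannot happen for m-sequences
            raise ValueError("degenerate waveform")
    else:
        scale = amplitude_pp / span
    if scale == 0.0:
        raise ValueError("all-zero symbol sequence integrates to a flat waveform; "
                         "cannot scale to the requested amplitude")
    return PerturbationSignal(
        states=states,
        dt_state=dt_state,
        velocity=vel * scale,
        position=pos * scale,
        fs=fs,
        period=len(states) * dt_state,
        amplitude_pp=amplitude_pp,
    )


def excited_frequencies(period: float = 20.0, f_max: float = 2.05) -> np.ndarray:
    """Odd harmonics of the fundamental 1/period up to and including f_max (Hz).

    For a 20 s period and f_max = 2.05 Hz this is 0.05, 0.15, ..., 2.05 Hz
    (21 frequencies) — the analysis band of the identification.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    f0 = 1.0 / period
    if f_max < f0:
        raise ValueError(f"f_max = {f_max} is below the fundamental {f0}")
    k_max = int(np.floor(f_max / f0 + 1e-9))
    ks = np.arange(1, k_max + 1, 2)
    return ks * f0
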