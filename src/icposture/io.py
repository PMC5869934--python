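"""On-disk formats: two-column trial CSVs and spectral-estimate tables.

Convention: angles are stored in degrees, time in seconds starting at 0.0,
0-based sample indexing; CSV for time series and tables, JSON for results,
YAML for configuration.  Radians are used only inside the library.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TimeSeries
from .sysid import SpectralEstimate

__all__ = ["read_trial", "write_trial", "write_spectral_table", "read_spectral_table"]

_TRIAL_COLUMNS = ["time_s", "ss_deg", "bs_deg"]
_JITTER_TOL_S = 1e-6


class TrialParseError(ValueError):
    """A trial CSV violated the format contract."""


def write_trial(path, ss: TimeSeries, bs: TimeSeries) -> None:
    """Write an (SS, BS) pair as a time_s,ss_deg,bs_deg CSV."""
    if len(ss) != len(bs) or abs(ss.fs - bs.fs) > 1e-12:
        raise ValueError("ss and bs must share length and sample rate")
    pd.DataFrame({"time_s": ss.t, "ss_deg": ss.y, "bs_deg": bs.y}).to_csv(
        path, index=False, float_format="%.10g")


def read_trial(path) -> tuple[TimeSeries, TimeSeries]:
    """Read and validate a trial CSV, inferring the sample rate.

    Rejects missing columns, NaN values and non-uniform time stamps (jitter
    above 1 µs), naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing columns {missing}")
    if df[_TRIAL_COLUMNS].isna().any().any():
        row = int(df[_TRIAL_COLUMNS].isna().any(axis=1).idxmax())
        raise TrialParseError(f"{path}: NaN value at row {row}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TrialParseError(f"{path}: need at least two samples")
    dt = np.diff(t)
    dt0 = np.median(dt)
    if dt0 <= 0:
        raise TrialParseError(f"{path}: non-increasing time column")
    bad = np.where(np.abs(dt - dt0) > _JITTER_TOL_S)[0]
    if bad.size:
        raise TrialParseError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 1} "
            f"(dt = {dt[bad[0]]:.9f} s, expected {dt0:.9f} s)")
    fs = 1.0 / dt0
    # snap to a round rate when within jitter tolerance (e.g. 999.999... -> 1000)
    if abs(fs - round(fs)) / fs < 1e-6:
        fs = float(round(fs))
    ss = TimeSeries(t=t, y=df["ss_deg"].to_numpy(dtype=float), fs=fs, label="SS")
    bs = TimeSeries(t=t, y=df["bs_deg"].to_numpy(dtype=float), fs=fs, label="BS")
    return ss, bs


def write_spectral_table(path, spec: SpectralEstimate) -> None:
    """Write an identified spectrum as freq_hz, re_H, im_H, magnitude,
    phase_deg, coherence CSV."""
    pd.DataFrame({
        "freq_hz": spec.freqs,
        "re_H": spec.frf.real,
        "im_H": spec.frf.imag,
        "magnitude": np.abs(spec.frf),
        "phase_deg": np.degrees(np.angle(spec.frf)),
        "coherence": spec.coherence,
    }).to_csv(path, index=False, float_format="%.10g")


def read_spectral_table(path) -> SpectralEstimate:
    """Read a spectral table written by :func:`write_spectral_table`.

    The block-level spectra are not stored in the table; the returned
    estimate carries the FRF and coherence (what the fit needs) with the
    per-block fields filled by their averaged equivalents.
    """
    df = pd.read_csv(path)
    freqs = df["freq_hz"].to_numpy(dtype=float)
    frf = df["re_H"].to_numpy(dtype=float) + 1j * df["im_H"].to_numpy(dtype=float)
    coh = df["coherence"].to_numpy(dtype=float)
    one = np.ones_like(freqs)
    return SpectralEstimate(
        freqs=freqs, frf=frf, coherence=coh,
        csd=frf, psd_ss=one, psd_bs=np.abs(frf) ** 2,
        n_blocks=1, even_fraction=float("nan"),
    )
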