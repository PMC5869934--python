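"""Independent Channel (IC) model of human stance control.

The body is a single inverted pendulum pivoting about the ankle joint,
stabilised by a neural PD controller acting through a lumped time delay on a
weighted sum of sensory "channels" (proprioceptive, visual, vestibular) plus
a low-pass-filtered positive torque feedback.  In the Laplace domain the four
blocks are

    BD(s) = 1 / (J s^2 - m g h)          body dynamics (inverted pendulum)
    NC(s) = K_P + K_D s                  neural controller (PD)
    TD(s) = exp(-tau_D s)                lumped time delay
    FF(s) = K_F / (tau_F s + 1)          positive force feedback

and the closed-loop sensitivity of body sway (BS) to a support-surface (SS)
rotation is

    H(s) = W_p NC TD BD / (1 - FF NC TD + NC TD BD)

which is the transfer function fitted to experimentally identified FRFs.
Internally everything is SI (radians, N·m, seconds); degrees appear only at
I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Anthropometry",
    "ICParameters",
    "Condition",
    "Eyes",
    "component_response",
    "closed_loop_sensitivity",
    "normalized_gains",
    "winter_anthropometry",
]

G_DEFAULT = 9.81

# Segment coefficients after Winter's anthropometric tables (fractions of
# total body mass M and stature H).  The foot segments are excluded: the
# "body" of the pendulum is everything above the ankle joint.  Frozen here as
# named constants so that derived anthropometry is deterministic.
WINTER_FOOT_MASS_FRACTION = 0.0145          # per foot, of M
WINTER_SHANK_MASS_FRACTION = 0.0465         # per shank, of M
WINTER_THIGH_MASS_FRACTION = 0.1000         # per thigh, of M
WINTER_HAT_MASS_FRACTION = 0.678            # head-arms-trunk, of M
WINTER_ANKLE_HEIGHT = 0.039                 # of H, above floor
WINTER_KNEE_HEIGHT = 0.285                  # of H
WINTER_HIP_HEIGHT = 0.530                   # of H (greater trochanter)
WINTER_SHOULDER_HEIGHT = 0.818              # of H (glenohumeral joint)
WINTER_SHANK_COM_FROM_PROXIMAL = 0.433      # of segment length
WINTER_THIGH_COM_FROM_PROXIMAL = 0.433      # of segment length
WINTER_HAT_COM_FROM_PROXIMAL = 0.626        # of trochanter-shoulder distance
WINTER_SHANK_ROG_COM = 0.302                # radius of gyration about CoM, of length
WINTER_THIGH_ROG_COM = 0.323
WINTER_HAT_ROG_COM = 0.496


@dataclass(frozen=True)
class Anthropometry:
    """Pendulum constants: mass (kg, body without feet), CoM height above the
    ankle axis (m), and moment of inertia about the ankle axis (kg m^2)."""

    m: float
    h: float
    J: float
    g: float = G_DEFAULT

    def __post_init__(self) -> None:
        for name in ("m", "h", "J", "g"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Anthropometry.{name} must be finite and > 0, got {v}")

    @property
    def mgh(self) -> float:
        """Gravitational stiffness m·g·h (N·m/rad), the destabilising torque
        gradient of the inverted pendulum."""
        return self.m * self.g * self.h


class Eyes(str, Enum):
    OPEN = "open"
    CLOSED = "closed"


@dataclass(frozen=True)
class Condition:
    """Experimental condition: peak-to-peak SS amplitude (deg) and visual state."""

    amplitude_deg: float
    eyes: Eyes

    def __post_init__(self) -> None:
        if not self.amplitude_deg > 0:
            raise ValueError(f"amplitude_deg must be > 0, got {self.amplitude_deg}")
        object.__setattr__(self, "eyes", Eyes(self.eyes))

    @property
    def label(self) -> str:
        return f"{self.amplitude_deg:g}deg_{self.eyes.value}"


_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class ICParameters:
    """Full IC parameter set: anthropometry plus sensory weights, PD gains,
    lumped delay and force feedback.

    The three sensory weights are fractions of the feedback signal and must
    sum to one.  ``K_P`` must exceed the gravitational stiffness m·g·h or the
    closed loop has no stable upright equilibrium.
    """

    anthropometry: Anthropometry
    W_p: float
    W_vis: float
    W_ves: float
    K_P: float          # reflexive stiffness, N·m/rad
    K_D: float          # reflexive damping, N·m·s/rad
    tau_D: float        # lumped time delay, s
    tau_F: float        # force-feedback time constant, s
    K_F: float          # force-feedback gain, rad/(N·m)

    def __post_init__(self) -> None:
        for name in ("W_p", "W_vis", "W_ves"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        s = self.W_p + self.W_vis + self.W_ves
        if abs(s - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"sensory weights must sum to 1 (got {s!r})")
        if self.K_P <= self.anthropometry.mgh:
            raise ValueError(
                f"K_P = {self.K_P:.3f} must exceed the gravitational stiffness "
                f"m·g·h = {self.anthropometry.mgh:.3f} for a stable upright equilibrium"
            )
        if self.K_D < 0:
            raise ValueError(f"K_D must be >= 0, got {self.K_D}")
        if self.tau_D < 0:
            raise ValueError(f"tau_D must be >= 0, got {self.tau_D}")
        if self.tau_F <= 0:
            raise ValueError(f"tau_F must be > 0, got {self.tau_F}")

    @classmethod
    def from_proprioceptive_weight(
        cls,
        anthropometry: Anthropometry,
        W_p: float,
        eyes: Eyes | str,
        **gains: float,
    ) -> "ICParameters":
        """Build a parameter set from W_p alone, assigning the complementary
        space-referenced weight 1 - W_p.

        Eyes closed forces W_vis = 0, so W_ves = 1 - W_p.  Eyes open the
        visual and vestibular contributions cannot be separated; the combined
        weight is carried in ``W_ves`` by convention (both channels sense the
        same body-in-space signal when the surround is earth-fixed, so the
        split does not affect the dynamics).
        """
        Eyes(eyes)  # validate
        return cls(anthropometry=anthropometry, W_p=W_p, W_vis=0.0, W_ves=1.0 - W_p, **gains)

    def to_dict(self) -> dict:
        a = self.anthropometry
        return {
            "m": a.m, "h": a.h, "J": a.J, "g": a.g,
            "W_p": self.W_p, "W_vis": self.W_vis, "W_ves": self.W_ves,
            "K_P": self.K_P, "K_D": self.K_D,
            "tau_D": self.tau_D, "tau_F": self.tau_F, "K_F": self.K_F,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ICParameters":
        anthro = Anthropometry(m=d["m"], h=d["h"], J=d["J"], g=d.get("g", G_DEFAULT))
        return cls(
            anthropometry=anthro,
            W_p=d["W_p"], W_vis=d["W_vis"], W_ves=d["W_ves"],
            K_P=d["K_P"], K_D=d["K_D"],
            tau_D=d["tau_D"], tau_F=d["tau_F"], K_F=d["K_F"],
        )

    def replace(self, **changes) -> "ICParameters":
        return replace(self, **changes)


_COMPONENTS = ("BD", "NC", "TD", "FF")


def component_response(component: str, params: ICParameters, f: float) -> complex:
    """Frequency response of one IC block (BD, NC, TD or FF) at frequency f (Hz).

    Evaluated at s = i 2π f.  BD is the linearised inverted pendulum
    (equation of motion J θ'' = m g h θ + T, so torque-to-angle transfer
    1/(J s^2 - m g h)); NC the PD controller; TD the pure delay; FF the
    first-order low-pass positive force feedback.
    """
    if component not in _COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected one of {_COMPONENTS}")
    if not np.isfinite(f):
        raise ValueError(f"frequency must be finite, got {f}")
    if f < 0:
        raise ValueError(f"frequency must be >= 0, got {f}")
    s = 1j * 2.0 * np.pi * f
    a = params.anthropometry
    if component == "BD":
        return complex(1.0 / (a.J * s**2 - a.mgh))
    if component == "NC":
        return complex(params.K_P + params.K_D * s)
    if component == "TD":
        return complex(np.exp(-params.tau_D * s))
    return complex(params.K_F / (params.tau_F * s + 1.0))


def closed_loop_sensitivity(params: ICParameters, freqs: Iterable[float]) -> np.ndarray:
    """Closed-loop SS-to-BS sensitivity H(f) of the IC model.

        H = W_p NC TD BD / (1 - FF NC TD + NC TD BD)

    evaluated element-wise at the requested frequencies (Hz).  Raises if the
    loop denominator is numerically singular at any frequency.
    """
    f = np.atleast_1d(np.asarray(freqs, dtype=float))
    if f.size == 0:
        raise ValueError("freqs must be non-empty")
    if np.any(~np.isfinite(f)) or np.any(f < 0):
        raise ValueError("freqs must be finite and >= 0")
    s = 1j * 2.0 * np.pi * f
    a = params.anthropometry
    bd = 1.0 / (a.J * s**2 - a.mgh)
    nc = params.K_P + params.K_D * s
    td = np.exp(-params.tau_D * s)
    ff = params.K_F / (params.tau_F * s + 1.0)
    den = 1.0 - ff * nc * td + nc * td * bd
    bad = np.abs(den) < 1e-12
    if np.any(bad):
        raise ZeroDivisionError(
            f"closed-loop denominator singular at f = {f[bad][0]:.6g} Hz"
        )
    return params.W_p * nc * td * bd / den


def normalized_gains(params: ICParameters) -> tuple[float, float]:
    """Reflexive stiffness and damping normalised to the gravitational
    stiffness m·g·h: (K_P/mgh, K_D/mgh)."""
    mgh = params.anthropometry.mgh
    return params.K_P / mgh, params.K_D / mgh


def winter_anthropometry(total_mass: float, total_height: float, g: float = G_DEFAULT) -> Anthropometry:
    """Derive pendulum constants from total body mass (kg) and stature (m)
    using the frozen Winter segment coefficients.

    The feet are excluded; m is the mass above the ankles, h the CoM height
    of that mass above the ankle axis, and J its moment of inertia about the
    ankle axis (parallel-axis sum over shanks, thighs and head-arms-trunk).
    """
    if not total_mass > 0 or not total_height > 0:
        raise ValueError("total_mass and total_height must be > 0")
    M, H = float(total_mass), float(total_height)

    # per-segment (mass, CoM height above floor, segment length) as fractions
    shank_len = WINTER_KNEE_HEIGHT - WINTER_ANKLE_HEIGHT
    thigh_len = WINTER_HIP_HEIGHT - WINTER_KNEE_HEIGHT
    hat_len = WINTER_SHOULDER_HEIGHT - WINTER_HIP_HEIGHT
    segments = [
        # (mass fraction, CoM height fraction, radius of gyration fraction of H)
        (2 * WINTER_SHANK_MASS_FRACTION,
         WINTER_KNEE_HEIGHT - WINTER_SHANK_COM_FROM_PROXIMAL * shank_len,
         WINTER_SHANK_ROG_COM * shank_len),
        (2 * WINTER_THIGH_MASS_FRACTION,
         WINTER_HIP_HEIGHT - WINTER_THIGH_COM_FROM_PROXIMAL * thigh_len,
         WINTER_THIGH_ROG_COM * thigh_len),
        (WINTER_HAT_MASS_FRACTION,
         WINTER_HIP_HEIGHT + WINTER_HAT_COM_FROM_PROXIMAL * hat_len,
         WINTER_HAT_ROG_COM * hat_len),
    ]
    m = M * sum(mf for mf, _, _ in segments)
    com_above_floor = sum(mf * cf for mf, cf, _ in segments) / sum(mf for mf, _, _ in segments)
    h = (com_above_floor - WINTER_ANKLE_HEIGHT) * H
    J = 0.0
    for mf, cf, rf in segments:
        mi = M * mf
        di = (cf - WINTER_ANKLE_HEIGHT) * H   # CoM distance to ankle axis
        ri = rf * H
        J += mi * (ri**2 + di**2)
    return Anthropometry(m=m, h=h, J=J, g=g)
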