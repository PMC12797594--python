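"""Discrete reference waveforms for the rank-based rhythm tests.

Three shapes are supported, all evaluated pointwise at the observed times so
regular and irregular sampling are handled identically:

* ``cosine`` -- cos(2*pi*(t - lag)/P);
* ``triangle`` -- a piecewise-linear wave in [0, 1] peaking at t = lag
  (mod P), rising over a fraction ``a`` of the cycle (``a`` = 0.5 is the
  symmetric tent, other values give asymmetric saw-like shapes);
* ``harmonic`` -- a two-component composite
  cos(2*pi*(t - lag)/P) + gamma*cos(4*pi*(t - harmonic_lag)/P), able to
  express bimodal waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TemplateSpecError

__all__ = [
    "TemplateSpec",
    "cosine_reference",
    "triangle_reference",
    "harmonic_reference",
    "build_template",
]


@dataclass(frozen=True)
class TemplateSpec:
    """Parameters of one reference waveform.

    ``lag`` is the peak-time offset in hours; ``asymmetry`` the rise
    fraction of the triangle cycle (0.5 = symmetric); ``harmonic_weight``
    (gamma >= 0) and ``harmonic_lag`` apply to the harmonic shape only.
    """

    shape: str
    period: float
    lag: float = 0.0
    asymmetry: float = 0.5
    harmonic_weight: float = 0.0
    harmonic_lag: float = 0.0

    def __post_init__(self):
        if self.shape not in ("triangle", "cosine", "harmonic"):
            raise TemplateSpecError(f"unknown template shape {self.shape!r}")
        if self.period <= 0:
            raise TemplateSpecError("period must be positive")
        if not (0.0 <= self.lag < self.period):
            raise TemplateSpecError("lag must lie in [0, period)")
        if self.shape == "triangle" and not (0.0 < self.asymmetry < 1.0):
            raise TemplateSpecError("asymmetry must lie strictly inside (0, 1)")
        if self.harmonic_weight < 0:
            raise TemplateSpecError("harmonic weight must be non-negative")


def cosine_reference(period: float, lag: float, times) -> np.ndarray:
    """cos(2*pi*(t - lag)/period) at the observed times."""
    if period <= 0:
        raise TemplateSpecError("period must be positive")
    t = np.asarray(times, dtype=float)
    return np.cos(2.0 * np.pi * (t - lag) / period)


def triangle_reference(period: float, lag: float, asymmetry: float, times) -> np.ndarray:
    """Asymmetric triangle wave in [0, 1], peak value 1 at t = lag (mod P).

    With cycle phase u = ((t - lag)/P + a) mod 1 the value is u/a on the
    rising branch (u <= a) and (1 - u)/(1 - a) on the falling branch.
    """
    if not (0.0 < asymmetry < 1.0):
        raise TemplateSpecError("asymmetry must lie strictly inside (0, 1)")
    t = np.asarray(times, dtype=float)
    u = ((t - lag) / period + asymmetry) % 1.0
    rising = u <= asymmetry
    out = np.where(rising, u / asymmetry, (1.0 - u) / (1.0 - asymmetry))
    return out


def harmonic_reference(
    period: float, lag1: float, gamma: float, lag2: float, times
) -> np.ndarray:
    """Two-component composite: fundamental plus gamma-weighted second
    harmonic, cos(2*pi*(t - lag1)/P) + gamma*cos(4*pi*(t - lag2)/P)."""
    if period <= 0:
        raise TemplateSpecError("period must be positive")
    if gamma < 0:
        raise TemplateSpecError("gamma must be non-negative")
    t = np.asarray(times, dtype=float)
    # same expression as cosine_reference so gamma = 0 reduces to it exactly
    fundamental = np.cos(2.0 * np.pi * (t - lag1) / period)
    if gamma == 0:
        return fundamental
    return fundamental + gamma * np.cos(4.0 * np.pi * (t - lag2) / period)


def build_template(spec: TemplateSpec, times) -> np.ndarray:
    """Evaluate a :class:`TemplateSpec` at the observed times."""
    if spec.shape == "triangle":
        return triangle_reference(spec.period, spec.lag, spec.asymmetry, times)
    if spec.shape == "cosine":
        return cosine_reference(spec.period, spec.lag, times)
    return harmonic_reference(
        spec.period, spec.lag, spec.harmonic_weight, spec.harmonic_lag, times
    )
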