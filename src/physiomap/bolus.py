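"""Gamma-variate bolus kinetics shared by the simulator and the DSC fitters.

The first pass of a contrast bolus through a voxel is modelled as

    g(t) = K * (t - t0)^alpha * exp(-(t - t0) / b)   for t > t0, else 0

with amplitude K, arrival time t0 (s), shape alpha and scale b (s).  The curve
peaks at t0 + alpha*b and has area K * Gamma(alpha+1) * b^(alpha+1).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma as gamma_fn

__all__ = [
    "gamma_variate",
    "unit_area_gamma",
    "gamma_variate_area",
    "gamma_variate_peak_time",
    "gamma_variate_peak_value",
]


def gamma_variate(t, K, t0, alpha, b):
    """Evaluate the gamma-variate bolus model; zero before arrival."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    out[pos] = K * dt[pos] ** alpha * np.exp(-dt[pos] / b)
    return out


def gamma_variate_area(K, t0, alpha, b):
    """Analytic area under the curve: K * Gamma(alpha+1) * b^(alpha+1)."""
    return K * gamma_fn(alpha + 1.0) * b ** (alpha + 1.0)


def gamma_variate_peak_time(t0, alpha, b):
    """Mode of the curve, t0 + alpha*b."""
    return t0 + alpha * b


def gamma_variate_peak_value(K, alpha, b):
    """Curve value at its mode."""
    return K * (alpha * b) ** alpha * np.exp(-alpha)


def unit_area_gamma(t, t0, alpha, b):
    """Gamma-variate normalised to unit area (a transit-time density)."""
    K = 1.0 / (gamma_fn(alpha + 1.0) * b ** (alpha + 1.0))
    return gamma_variate(t, K, t0, alpha, b)
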