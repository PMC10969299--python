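"""Vascular architecture mapping from paired GE/SE first-pass curves.

The vascular hysteresis loop (VHL) is the parametric curve of dR2,GE against
(dR2,SE)^(3/2) over the bolus first pass.  Its signed area is the microvessel
type indicator (MTI): clockwise traversal (x right, y up) is positive and
marks arteriole-dominated vasculature, counter-clockwise negative traversal
marks venule/capillary-dominated vasculature.  From the curve maxima,

    Q_max = max[dR2,GE] / max[(dR2,SE)^(3/2)]

and with CBV and ADC the semi-empirical microvessel density and vessel size
index follow:

    MVD = (Q_max / beta) * [CBV / (2^4 pi^2 ADC R^4)]^(1/3)      [mm^-2]
    VSI = [CBV * ADC * beta^3 / (2 pi Q_max^3)]^(1/2)            [mm]

The printed typography of these relations admits more than one grouping; the
grouping above is the package's canonical parse, implemented in single
formula functions and recorded as ``parse`` metadata with each output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import VamConstants

__all__ = ["HysteresisLoop", "build_vhl", "compute_qmax", "compute_mti",
           "compute_mvd", "compute_vsi", "MVD_PARSE", "VSI_PARSE", "QMAX_PARSE"]

MVD_PARSE = "MVD=(Qmax/beta)*(CBV/(2^4*pi^2*ADC*R^4))^(1/3)"
VSI_PARSE = "VSI=(CBV*ADC*beta^3/(2*pi*Qmax^3))^(1/2)"
QMAX_PARSE = "Qmax=max[dR2ge]/max[dR2se^(3/2)]"


@dataclass
class HysteresisLoop:
    """Ordered VHL points (x = (dR2,SE)^(3/2), y = dR2,GE), closed last-to-first."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("loop coordinates must have equal length")
        if self.x.size < 8:
            raise ValueError("hysteresis loop requires at least 8 points")


def build_vhl(ge_curve: np.ndarray, se_curve: np.ndarray,
              times_ge: np.ndarray | None = None,
              times_se: np.ndarray | None = None) -> HysteresisLoop:
    """Build the vascular hysteresis loop from first-pass GE and SE curves.

    The curves must share a time base (checked when both are supplied).
    Negative SE excursions are floored at 0 before the 3/2 power.
    """
    if times_ge is not None and times_se is not None:
        if len(times_ge) != len(times_se) or not np.allclose(times_ge, times_se):
            raise ValueError("GE and SE curves must share a time base")
    ge = np.asarray(ge_curve, dtype=float)
    se = np.asarray(se_curve, dtype=float)
    if ge.shape != se.shape:
        raise ValueError("GE and SE curves must share a time base")
    return HysteresisLoop(np.maximum(se, 0.0) ** 1.5, ge)


def compute_qmax(ge_curve: np.ndarray, se_curve: np.ndarray):
    """Q_max = max[dR2,GE] / max[(dR2,SE)^(3/2)].

    Returns ``(qmax, valid)``; a nonpositive SE maximum flags the result.
    """
    ge = np.asarray(ge_curve, dtype=float)
    se = np.maximum(np.asarray(se_curve, dtype=float), 0.0)
    ge_max = ge.max(axis=-1)
    se_max = (se ** 1.5).max(axis=-1)
    valid = (se_max > 0) & (ge_max > 0)
    qmax = np.where(valid, ge_max / np.where(valid, se_max, 1.0), 0.0)
    if np.ndim(qmax) == 0:
        return float(qmax), bool(valid)
    return qmax, valid


def compute_mti(loop: HysteresisLoop) -> float:
    """Signed VHL area by the shoelace formula.

    Clockwise traversal in the conventional x-right/y-up plane gives a
    positive value, counter-clockwise a negative one; reversing the point
    order flips the sign exactly.
    """
    x, y = loop.x, loop.y
    if x.size < 3:
        raise ValueError("signed area requires at least 3 points")
    # standard shoelace is positive for counter-clockwise; MTI negates it
    ccw = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(-ccw)


def mti_from_curves(ge: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Vectorised signed VHL area for stacked curves of shape (..., t)."""
    x = np.maximum(np.asarray(se, dtype=float), 0.0) ** 1.5
    y = np.asarray(ge, dtype=float)
    ccw = 0.5 * np.sum(x * np.roll(y, -1, axis=-1) - np.roll(x, -1, axis=-1) * y, axis=-1)
    return -ccw


def compute_mvd(qmax, cbv, adc, consts: VamConstants = VamConstants()):
    """Microvessel density in mm^-2 under the canonical parse.

    ADC is in mm^2/s and the mean vessel radius in mm.  Returns
    ``(mvd, valid)``; nonpositive inputs are flagged.
    """
    qmax, cbv, adc = (np.asarray(v, dtype=float) for v in (qmax, cbv, adc))
    valid = (qmax > 0) & (cbv > 0) & (adc > 0)
    denom = 2.0**4 * np.pi**2 * np.where(adc > 0, adc, 1.0) * consts.mean_radius_mm**4
    mvd = np.where(valid, (qmax / consts.beta) * (np.where(valid, cbv, 0.0) / denom) ** (1.0 / 3.0), 0.0)
    if np.ndim(mvd) == 0:
        return float(mvd), bool(valid)
    return mvd, valid


def compute_vsi(cbv, adc, qmax, consts: VamConstants = VamConstants()):
    """Vessel size index in mm under the canonical parse.

    Returns ``(vsi, valid)``; Q_max = 0 voxels are flagged.
    """
    qmax, cbv, adc = (np.asarray(v, dtype=float) for v in (qmax, cbv, adc))
    valid = (qmax > 0) & (cbv >= 0) & (adc >= 0)
    q3 = np.where(valid, qmax, 1.0) ** 3
    vsi = np.where(valid, np.sqrt(cbv * adc * consts.beta**3 / (2.0 * np.pi * q3)), 0.0)
    if np.ndim(vsi) == 0:
        return float(vsi), bool(valid)
    return vsi, valid
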