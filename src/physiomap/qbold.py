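"""qBOLD oxygen-metabolism biomarker maps.

From the relaxation-rate difference R2' = R2* - R2 and the blood-volume
fraction, four biomarkers are derived voxelwise:

    OEF     = (R2* - R2) / (k * CBV),     k = (4/3) pi gamma dchi Hct B0
    CMRO2   = Ca * CBF * OEF              (Fick's principle)
    capiPO2 = P50 * (2/OEF - 1)^(1/h)     (Hill model of O2-Hb dissociation)
    mitoPO2 = capiPO2 - CMRO2 / L

OEF is clamped to the physical range [0, 1]; mitoPO2 is floored at 0.  Each
output carries a validity mask; degenerate voxels (CBV = 0, OEF = 0 where a
divergent power would result, negative tensions) are flagged rather than
propagated as infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import PhysioConstants

__all__ = ["OxygenMaps", "compute_oef", "compute_cmro2", "compute_capipo2",
           "compute_mitopo2", "compute_oxygen_maps"]


@dataclass
class OxygenMaps:
    """The four oxygen-metabolism maps with a shared validity mask."""

    oef: np.ndarray
    cmro2: np.ndarray
    capipo2: np.ndarray
    mitopo2: np.ndarray
    valid: np.ndarray


def _as_arrays(*xs):
    return [np.asarray(x, dtype=float) for x in xs]


def compute_oef(r2star, r2, cbv, consts: PhysioConstants = PhysioConstants()):
    """Oxygen extraction fraction map with validity flags.

    Returns ``(oef, valid)``; OEF is clamped to [0, 1] and voxels with
    nonpositive CBV (or an out-of-range raw quotient) are flagged.
    """
    r2star, r2, cbv = _as_arrays(r2star, r2, cbv)
    valid = cbv > 0
    denom = np.where(valid, consts.k * cbv, 1.0)
    raw = np.where(valid, (r2star - r2) / denom, 0.0)
    oef = np.clip(raw, 0.0, 1.0)
    valid = valid & (raw >= 0.0) & (raw <= 1.0)
    return oef, valid


def compute_cmro2(cbf, oef, consts: PhysioConstants = PhysioConstants()):
    """Cerebral metabolic rate of oxygen, CMRO2 = Ca * CBF * OEF.

    With k chosen as in :class:`PhysioConstants` the rate-difference form
    Ca * CBF * (R2*-R2) / (k * CBV) reduces identically to this product, so
    the OEF map is consumed directly.  Units are Ca x flow units.
    """
    cbf, oef = _as_arrays(cbf, oef)
    return consts.ca * cbf * oef


def compute_capipo2(oef, consts: PhysioConstants = PhysioConstants()):
    """Capillary oxygen tension, capiPO2 = P50 * (2/OEF - 1)^(1/h), in mmHg.

    Returns ``(capipo2, valid)``; the expression diverges as OEF -> 0, so
    nonpositive-OEF voxels are flagged invalid and set to 0.  At OEF = 1 the
    power term is exactly 1 and capiPO2 equals the half-saturation tension.
    """
    oef = np.asarray(oef, dtype=float)
    valid = oef > 0
    safe = np.where(valid, oef, 1.0)
    capipo2 = np.where(valid, consts.p50 * (2.0 / safe - 1.0) ** (1.0 / consts.hill), 0.0)
    return capipo2, valid


def compute_mitopo2(capipo2, cmro2, consts: PhysioConstants = PhysioConstants()):
    """Mitochondrial oxygen tension, mitoPO2 = capiPO2 - CMRO2/L, in mmHg.

    Returns ``(mitopo2, clamped)``: negative differences are floored at 0 and
    reported in the ``clamped`` flag array.
    """
    capipo2, cmro2 = _as_arrays(capipo2, cmro2)
    raw = capipo2 - cmro2 / consts.conductivity
    clamped = raw < 0
    return np.where(clamped, 0.0, raw), clamped


def compute_oxygen_maps(r2star, r2, cbv, cbf,
                        consts: PhysioConstants = PhysioConstants()) -> OxygenMaps:
    """All four qBOLD biomarker maps from rate, volume and flow maps."""
    oef, v_oef = compute_oef(r2star, r2, cbv, consts)
    cmro2 = compute_cmro2(cbf, oef, consts)
    capipo2, v_cap = compute_capipo2(oef, consts)
    mitopo2, _ = compute_mitopo2(capipo2, cmro2, consts)
    return OxygenMaps(oef, cmro2, capipo2, mitopo2, valid=v_oef & v_cap)
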