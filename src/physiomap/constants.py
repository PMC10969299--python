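"""Physical and physiological constants of the qBOLD and vessel-architecture models.

The qBOLD constants enter through the static-dephasing relation between the
reversible relaxation-rate offset R2' = R2* - R2 and the deoxygenated blood
volume, R2' = k * CBV * OEF with k = (4/3) * pi * gamma * dchi * Hct * B0.
The same k is used in the oxygen-turnover relation so that CMRO2 reduces to
Fick's principle, CMRO2 = Ca * CBF * OEF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

__all__ = ["PhysioConstants", "VamConstants", "QBOLD_K"]


@dataclass(frozen=True)
class PhysioConstants:
    """Constants of the oxygen-metabolism model.

    Attributes
    ----------
    delta_chi
        Susceptibility difference between fully oxygenated and fully
        deoxygenated haemoglobin (dimensionless, SI).
    hct
        Microvascular haematocrit; systemic 0.42 scaled by the 0.85
        small-vessel correction factor.
    gamma
        Proton gyromagnetic ratio, rad/s/T.
    b0
        Static field strength, tesla.
    ca
        Arterial blood oxygen content (carried in its printed unit,
        "mmol/mL"; CMRO2 is reported in Ca x flow units without conversion).
    hill
        Hill coefficient of O2-haemoglobin binding.
    p50
        Haemoglobin half-saturation oxygen tension, mmHg.
    conductivity
        Tissue oxygen conductivity L, mmol/Hg per minute.
    """

    delta_chi: float = 0.264e-6
    hct: float = 0.42 * 0.85
    gamma: float = 2.67502e8
    b0: float = 3.0
    ca: float = 8.68
    hill: float = 2.7
    p50: float = 27.0
    conductivity: float = 4.4

    @property
    def k(self) -> float:
        """Static-dephasing proportionality k = (4/3)*pi*gamma*dchi*Hct*B0 (s^-1 per unit CBV)."""
        return (4.0 / 3.0) * math.pi * self.gamma * self.delta_chi * self.hct * self.b0


#: k evaluated at the default constants, ~316.8 s^-1 per unit blood-volume fraction.
QBOLD_K: float = PhysioConstants().k


@dataclass(frozen=True)
class VamConstants:
    """Constants of the microvessel density / vessel size relations.

    ``beta`` is a numerical constant of the semi-empirical model and
    ``mean_radius_mm`` the mean vessel lumen radius (3.0 um, stored in mm so
    that MVD comes out in mm^-2 and VSI in mm).
    """

    beta: float = 1.6781
    mean_radius_mm: float = 3.0e-3

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.mean_radius_mm <= 0:
            raise ValueError("VamConstants must be strictly positive")
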