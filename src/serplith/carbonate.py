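"""Carbonate speciation, Davies activity coefficients, and carbonate
mineral saturation.

In hyperalkaline (pH > 10) serpentinite springs nearly all dissolved
inorganic carbon sits in the carbonate/bicarbonate pools, so the CO2(aq)
available to autotrophs collapses to sub-nanomolar levels.  This module
partitions total inorganic carbon (TIC) among CO2(aq), HCO3- and CO3^2-
using temperature-adjusted dissociation constants (van 't Hoff), with an
optional Davies-equation activity correction, and computes the carbonate
concentration threshold above which CaCO3 precipitates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError
from .species import R, T_REF, ConstantsTable, load_constants

__all__ = [
    "CarbonateState", "SaturationResult", "speciate",
    "davies_log_gamma", "debye_huckel_a", "saturation_threshold",
]

# Fallback dissociation constants (molar scale, freshwater) used when a
# constants table is not supplied: pK at 298.15 K and dissociation
# enthalpy in kJ/mol.
_DEFAULT_EQUILIBRIA = {
    "K1_carbonic": (6.35, 7.64),
    "K2_carbonic": (10.33, 14.85),
    "Ks_calcite": (8.48, -12.3),
}


@dataclass(frozen=True)
class CarbonateState:
    """Equilibrium partition of TIC at fixed pH."""

    co2_aq: float   # mol/L
    hco3: float     # mol/L
    co3: float      # mol/L
    fractions: tuple  # (x_CO2, x_HCO3, x_CO3), sums to 1
    pK1: float      # temperature-adjusted
    pK2: float

    @property
    def tic(self) -> float:
        return self.co2_aq + self.hco3 + self.co3


@dataclass(frozen=True)
class SaturationResult:
    threshold: float          # mol/L CO3^2- needed for precipitation
    Ks: float
    cation: float             # mol/L
    co3: Optional[float] = None

    @property
    def saturated(self) -> Optional[bool]:
        if self.co3 is None:
            return None
        return self.co3 >= self.threshold


def debye_huckel_a(temperature: float) -> float:
    """Debye-Hückel A parameter (log10 basis) for water.

    Quadratic fit in Celsius to standard tabulations (0.4913 at 0 °C,
    0.5095 at 25 °C, 0.534 at 50 °C); adequate for 0-60 °C.
    """
    t = temperature - 273.15
    return 0.4913 + 5.99e-4 * t + 5.2e-6 * t * t


def davies_log_gamma(charge: int, ionic_strength: float,
                     temperature: float = T_REF) -> float:
    """log10 of the Davies activity coefficient.

    gamma = 1 exactly for neutral species or at zero ionic strength.
    """
    if ionic_strength < 0:
        raise ConfigError("ionic strength must be >= 0")
    if charge == 0 or ionic_strength == 0:
        return 0.0
    a = debye_huckel_a(temperature)
    s = math.sqrt(ionic_strength)
    return -a * charge * charge * (s / (1.0 + s) - 0.3 * ionic_strength)


def _vant_hoff_pk(pk_ref: float, dH: float, temperature: float) -> float:
    """Shift a pK from 298.15 K to ``temperature`` using van 't Hoff."""
    ln_k = -pk_ref * math.log(10.0) - (dH / R) * (1.0 / temperature - 1.0 / T_REF)
    return -ln_k / math.log(10.0)


def speciate(pH: float, tic: float, temperature: float = T_REF,
             ionic_strength: float = 0.0, activity_model: str = "ideal",
             constants: Optional[ConstantsTable] = None) -> CarbonateState:
    """Partition TIC among CO2(aq)/HCO3-/CO3^2- at fixed pH.

    ``activity_model`` is ``"ideal"`` (all gamma = 1) or ``"davies"``
    (charged species corrected; CO2(aq) is neutral, gamma = 1).  pH is
    interpreted as the H+ *activity* (NBS convention).  Outputs are
    free-ion concentrations.
    """
    if tic < 0:
        raise ConfigError("TIC must be >= 0")
    if activity_model not in ("ideal", "davies"):
        raise ConfigError(f"unknown activity model {activity_model!r}")
    eq = constants.equilibria if constants is not None and constants.equilibria \
        else _DEFAULT_EQUILIBRIA
    pk1 = _vant_hoff_pk(*eq["K1_carbonic"], temperature)
    pk2 = _vant_hoff_pk(*eq["K2_carbonic"], temperature)
    h = 10.0 ** (-pH)
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)
    if activity_model == "davies":
        g1 = 10.0 ** davies_log_gamma(1, ionic_strength, temperature)
        g2 = 10.0 ** davies_log_gamma(2, ionic_strength, temperature)
    else:
        g1 = g2 = 1.0
    # Mass action with activities: K1 = aH * (g1 [HCO3]) / [CO2];
    # K2 = aH * (g2 [CO3]) / (g1 [HCO3]).
    r1 = k1 / (h * g1)            # [HCO3]/[CO2]
    r2 = k1 * k2 / (h * h * g2)   # [CO3]/[CO2]
    denom = 1.0 + r1 + r2
    x_co2 = 1.0 / denom
    x_hco3 = r1 / denom
    x_co3 = r2 / denom
    return CarbonateState(
        co2_aq=tic * x_co2, hco3=tic * x_hco3, co3=tic * x_co3,
        fractions=(x_co2, x_hco3, x_co3), pK1=pk1, pK2=pk2,
    )


def saturation_threshold(Ks: float, cation: float,
                         co3: Optional[float] = None) -> SaturationResult:
    """Minimum carbonate concentration for CaCO3 precipitation,
    threshold = Ks / [Ca2+] (molar scale)."""
    if cation <= 0:
        raise ConfigError("cation concentration must be > 0")
    if Ks < 0:
        raise ConfigError("Ks must be >= 0")
    return SaturationResult(threshold=Ks / cation, Ks=Ks, cation=cation, co3=co3)
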