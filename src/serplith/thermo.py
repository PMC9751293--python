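"""In situ Gibbs free energies of aqueous reactions.

The pipeline composes four pieces, each exposed on its own:

* ``standard_reaction_energy`` — ΔG°298 from tabulated formation energies,
* ``gibbs_helmholtz_adjust``   — temperature rescaling using ΔH°298,
* ``reaction_quotient_term``   — RT·ln Q from site activities,
* ``pressure_adjust``          — optional linear ΔV°·(P − 1) term.

Energies are kJ per mole of the reaction's basis species.  Water has
unit activity; H+ activity comes from pH; every other solute must have a
concentration in the site conditions (there is no silent unit-activity
default).  A zero concentration makes ln Q diverge; that case is
returned as a tagged :class:`Unbounded` value rather than an IEEE
infinity so downstream viability logic must handle it explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from .carbonate import davies_log_gamma
from .conditions import SiteConditions, TIC_KEY
from .errors import ConfigError, MissingConcentrationError
from .species import R, T_REF, ConstantsTable, Reaction

__all__ = [
    "ReactionEnergy", "Unbounded", "standard_reaction_energy",
    "standard_reaction_enthalpy", "gibbs_helmholtz_adjust",
    "reaction_quotient_term", "delta_g_in_situ", "biochemical_standard",
    "pressure_adjust",
]


@dataclass(frozen=True)
class Unbounded:
    """Tagged divergent energy term.

    ``direction`` is +1 when ΔG → +∞ (a reactant at zero concentration:
    the reaction cannot proceed) and -1 when ΔG → -∞ (a product at
    zero: unboundedly favorable).
    """

    direction: int
    species: str

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


EnergyTerm = Union[float, Unbounded]


@dataclass(frozen=True)
class ReactionEnergy:
    """Fully decomposed energy of one reaction at one site.

    ``dG_insitu = dG0_T + rt_lnQ + pressure_term`` by construction.
    """

    reaction: str
    basis_species: str
    dG0_298: float
    dG0_T: float
    dG0_prime: float
    rt_lnQ: EnergyTerm
    pressure_term: float = 0.0

    @property
    def dG_insitu(self) -> EnergyTerm:
        if isinstance(self.rt_lnQ, Unbounded):
            return self.rt_lnQ
        return self.dG0_T + self.rt_lnQ + self.pressure_term


def _per_basis(total: float, reaction: Reaction) -> float:
    return total / reaction.basis_coefficient


def standard_reaction_energy(reaction: Reaction,
                             constants: ConstantsTable) -> float:
    """ΔG°298 = Σ ν·ΔG°f, kJ per mol basis species.

    Validates element/charge balance first (raises ``BalanceError``);
    unknown species raise ``MissingSpeciesError`` naming the species.
    """
    reaction.validate_balance(constants)
    total = sum(coeff * constants[name].dGf298
                for name, coeff in reaction.stoichiometry.items())
    return _per_basis(total, reaction)


def standard_reaction_enthalpy(reaction: Reaction,
                               constants: ConstantsTable) -> float:
    """ΔH°298 = Σ ν·ΔH°f, kJ per mol basis species."""
    reaction.validate_balance(constants)
    total = sum(coeff * constants[name].dHf298
                for name, coeff in reaction.stoichiometry.items())
    return _per_basis(total, reaction)


def gibbs_helmholtz_adjust(dG0_298: float, dH0_298: float,
                           temperature: float) -> float:
    """Rescale a standard ΔG from 298.15 K to ``temperature``:

    ΔG°(T) = ΔG°298·(T/T0) + ΔH°298·(1 − T/T0), T0 = 298.15 K.

    This is the integrated Gibbs–Helmholtz relation under constant ΔH°.
    """
    if temperature <= 0:
        raise ConfigError("temperature must be > 0 K")
    ratio = temperature / T_REF
    return dG0_298 * ratio + dH0_298 * (1.0 - ratio)


def _activity(name: str, coeff: float, conditions: SiteConditions,
              constants: ConstantsTable, activity_model: str) -> EnergyTerm:
    """ln-activity contribution bookkeeping helper: returns the activity
    of one species, or an :class:`Unbounded` tag when it is zero."""
    sp = constants[name]
    if sp.is_water:
        return 1.0
    if name == "H+":
        return conditions.proton_activity
    conc = conditions.concentrations.get(name)
    if conc is None:
        raise MissingConcentrationError(name, conditions.site_name)
    if conc == 0.0:
        # zero reactant (coeff < 0) pushes Q, hence dG, to +inf
        return Unbounded(direction=+1 if coeff < 0 else -1, species=name)
    gamma = 1.0
    if activity_model == "davies" and sp.charge != 0:
        gamma = 10.0 ** davies_log_gamma(sp.charge, conditions.ionic_strength,
                                         conditions.temperature)
    return conc * gamma


def reaction_quotient_term(reaction: Reaction, conditions: SiteConditions,
                           constants: ConstantsTable,
                           activity_model: str = "ideal") -> EnergyTerm:
    """RT·ln Q, kJ per mol basis species.

    Activities default to molar concentrations (γ = 1); the Davies model
    corrects charged solutes.  Water activity is fixed at 1 and H+ comes
    from pH.
    """
    if activity_model not in ("ideal", "davies"):
        raise ConfigError(f"unknown activity model {activity_model!r}")
    ln_q = 0.0
    for name, coeff in reaction.stoichiometry.items():
        act = _activity(name, coeff, conditions, constants, activity_model)
        if isinstance(act, Unbounded):
            return act
        ln_q += coeff * math.log(act)
    return _per_basis(R * conditions.temperature * ln_q, reaction)


def biochemical_standard(reaction: Reaction, constants: ConstantsTable,
                         temperature: float = T_REF) -> float:
    """Biochemical-standard ΔG°′: pH 7, all other activities 1.

    ΔG°′ = ΔG°(T) + ν_H+ · RT·ln(10⁻⁷), with ν_H+ the signed H+
    coefficient.  Default temperature is 298.15 K; pass the in situ
    temperature to report ΔG°′ on that basis.
    """
    dg0 = standard_reaction_energy(reaction, constants)
    if temperature != T_REF:
        dh0 = standard_reaction_enthalpy(reaction, constants)
        dg0 = gibbs_helmholtz_adjust(dg0, dh0, temperature)
    nu_h = reaction.stoichiometry.get("H+", 0.0)
    return dg0 + (nu_h / reaction.basis_coefficient) * R * temperature \
        * math.log(1e-7)


def pressure_adjust(dG: float, reaction: Reaction, pressure: float,
                    constants: Optional[ConstantsTable] = None,
                    enabled: bool = False) -> float:
    """Linear pressure correction dG + ΔV°·(P − 1 bar).

    Disabled by default: the springs this package models are sampled at
    ~1 bar, where the term vanishes.  When enabled, every participating
    species needs a molar volume (cm³/mol); 1 cm³·bar = 1e-4 kJ.
    """
    if not enabled or pressure == 1.0:
        return dG
    if constants is None:
        raise ConfigError("pressure correction enabled but no constants given")
    dv = 0.0
    for name, coeff in reaction.stoichiometry.items():
        sp = constants[name]
        if name == "H+":
            continue  # conventionally zero
        if sp.molar_volume is None:
            raise ConfigError(
                f"pressure correction enabled but species {name!r} has no "
                "molar volume")
        dv += coeff * sp.molar_volume
    dv /= reaction.basis_coefficient
    return dG + dv * (pressure - 1.0) * 1e-4


def delta_g_in_situ(reaction: Reaction, conditions: SiteConditions,
                    constants: ConstantsTable, activity_model: str = "ideal",
                    pressure_correction: bool = False) -> ReactionEnergy:
    """Full in situ energy decomposition for one reaction at one site.

    CO2(aq)/HCO3-/CO3^2- are derived from TIC when not given explicitly
    (same activity model as the quotient).
    """
    conditions = conditions.with_carbonate(constants, activity_model)
    dg0_298 = standard_reaction_energy(reaction, constants)
    dh0_298 = standard_reaction_enthalpy(reaction, constants)
    dg0_t = gibbs_helmholtz_adjust(dg0_298, dh0_298, conditions.temperature)
    rt_lnq = reaction_quotient_term(reaction, conditions, constants,
                                    activity_model)
    p_term = 0.0
    if pressure_correction:
        p_term = pressure_adjust(0.0, reaction, conditions.pressure,
                                 constants, enabled=True)
    return ReactionEnergy(
        reaction=reaction.name,
        basis_species=reaction.basis_species,
        dG0_298=dg0_298,
        dG0_T=dg0_t,
        dG0_prime=biochemical_standard(reaction, constants),
        rt_lnQ=rt_lnq,
        pressure_term=p_term,
    )
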