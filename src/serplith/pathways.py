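"""Candidate lithotrophic catabolisms and their viability in situ.

A :class:`Pathway` bundles a net reaction with an ATP ledger (substrate
level entries are integral, chemiosmotic ones fractional).  Viability
follows the bioenergetic quantum hypothesis: a catabolism is usable when
its in situ ΔG is at or below a threshold, −20 kJ per mol reaction by
default (inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .conditions import SiteConditions
from .errors import ConfigError
from .species import R, ConstantsTable, Reaction, ThermoSpecies
from .thermo import ReactionEnergy, Unbounded, delta_g_in_situ

__all__ = [
    "Pathway", "ViabilityReport", "CARRIER_SPECIES", "with_carriers",
    "load_pathways", "evaluate_pathway", "atp_per_h2",
    "atp_invested_variant", "donor_oxidation_favorability", "sensitivity",
    "VIABILITY_THRESHOLD", "DEFAULT_CARRIER_POTENTIALS",
]

#: default catabolic viability threshold, kJ per mol basis species
VIABILITY_THRESHOLD = -20.0

#: Faraday constant, kJ/(V·mol)
F = 96.485

# Abstract electron carriers / phosphoryl bookkeeping species used only
# inside pathway step lists.  Their formulas track H and charge so every
# internal step passes balance validation; they carry no energetics.
CARRIER_SPECIES = [
    ThermoSpecies("NADP_ox", {}, 1),
    ThermoSpecies("NADP_red", {"H": 1}, 0),
    ThermoSpecies("Trx_ox", {}, 0),
    ThermoSpecies("Trx_red", {"H": 2}, 0),
    ThermoSpecies("acetyl_phosphate", {"C": 2, "H": 4, "O": 2}, 0),
    ThermoSpecies("ADP", {}, 0),
    ThermoSpecies("ATP", {}, 0),
]


def with_carriers(constants: ConstantsTable) -> ConstantsTable:
    """Constants table extended with the abstract carrier species."""
    return ConstantsTable(list(constants) + CARRIER_SPECIES,
                          constants.equilibria)


@dataclass(frozen=True)
class Pathway:
    name: str
    net_reaction: Reaction
    atp_ledger: Tuple[Tuple[str, float], ...]
    h2_per_basis: float
    notes: str = ""
    condition_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)
    internal_steps: Tuple[Reaction, ...] = ()
    atp_investment: Optional[Tuple[int, float]] = None  # (n_atp, kJ/mol ATP)

    @property
    def net_atp(self) -> float:
        return sum(delta for _, delta in self.atp_ledger)

    def conditions_for(self, conditions: SiteConditions) -> SiteConditions:
        """Apply any per-site concentration overrides this pathway declares."""
        over = self.condition_overrides.get(conditions.site_name)
        return conditions.with_concentrations(over) if over else conditions

    def validate(self, constants: ConstantsTable) -> None:
        ext = with_carriers(constants)
        self.net_reaction.validate_balance(constants)
        for step in self.internal_steps:
            step.validate_balance(ext)
        h2 = abs(self.net_reaction.stoichiometry.get("H2(aq)", 0.0))
        if not math.isclose(h2, self.h2_per_basis *
                            self.net_reaction.basis_coefficient):
            raise ConfigError(
                f"{self.name}: h2_per_basis {self.h2_per_basis} does not "
                f"match the net reaction's H2 coefficient {h2}")


@dataclass(frozen=True)
class ViabilityReport:
    pathway: str
    dG_insitu: Union[float, Unbounded]
    threshold: float
    atp_per_h2: Optional[float]
    energy: Optional[ReactionEnergy] = None
    reason: str = ""

    @property
    def viable(self) -> bool:
        if isinstance(self.dG_insitu, Unbounded):
            return self.dG_insitu.direction < 0
        return self.dG_insitu <= self.threshold

    @property
    def margin(self) -> Optional[float]:
        if isinstance(self.dG_insitu, Unbounded):
            return None
        return self.dG_insitu - self.threshold


def _pathway_from_dict(d: Mapping, name_hint: str) -> Pathway:
    name = d.get("name", name_hint)
    reaction = Reaction(name=name, stoichiometry=dict(d["reaction"]),
                        basis_species=d["basis"])
    ledger = tuple((entry["step"], float(entry["atp"]))
                   for entry in d.get("atp_ledger", []))
    steps = tuple(
        Reaction(name=s["name"], stoichiometry=dict(s["stoichiometry"]),
                 basis_species=next(iter(s["stoichiometry"])))
        for s in d.get("internal_steps", []))
    return Pathway(
        name=name,
        net_reaction=reaction,
        atp_ledger=ledger,
        h2_per_basis=float(d.get("h2_per_basis", 0)),
        notes=str(d.get("description", "")),
        condition_overrides={
            site: dict(over)
            for site, over in (d.get("condition_overrides") or {}).items()},
        internal_steps=steps,
    )


def load_pathways(constants: Optional[ConstantsTable] = None
                  ) -> Dict[str, Pathway]:
    """Load the packaged pathway registry; every entry is balance-checked
    at load time when a constants table is given."""
    docs = []
    pkg = resources.files("serplith.data").joinpath("pathways")
    for ref in sorted(pkg.iterdir(), key=lambda r: r.name):
        if ref.name.endswith(".yaml"):
            with ref.open("r", encoding="utf-8") as fh:
                docs.append((ref.name, yaml.safe_load(fh)))
    registry: Dict[str, Pathway] = {}
    variants = []
    for fname, doc in docs:
        if "base" in doc:
            variants.append(doc)
        else:
            pw = _pathway_from_dict(doc, fname.rsplit(".", 1)[0])
            registry[pw.name] = pw
    for doc in variants:
        base = registry[doc["base"]]
        inv = doc["atp_investment"]
        registry[doc["name"]] = _apply_investment(
            base, doc["name"], int(inv["n_atp"]),
            float(inv["atp_hydrolysis_kj"]))
    if constants is not None:
        for pw in registry.values():
            pw.validate(constants)
    return registry


def _apply_investment(base: Pathway, name: str, n_atp: int,
                      atp_dg: float) -> Pathway:
    if n_atp < 0:
        raise ConfigError("n_atp must be >= 0")
    if n_atp and atp_dg >= 0:
        raise ConfigError("ATP hydrolysis energy must be negative")
    ledger = base.atp_ledger + ((f"ATP investment ({n_atp})", -float(n_atp)),)
    return Pathway(
        name=name, net_reaction=base.net_reaction, atp_ledger=ledger,
        h2_per_basis=base.h2_per_basis,
        notes=f"{base.notes} [{n_atp} ATP invested at {atp_dg} kJ/mol]",
        condition_overrides=base.condition_overrides,
        internal_steps=base.internal_steps,
        atp_investment=(n_atp, atp_dg),
    )


def atp_per_h2(pathway: Pathway) -> float:
    """Net ATP recovered per mol H2 oxidized."""
    if not pathway.atp_ledger:
        return 0.0
    if pathway.h2_per_basis <= 0:
        raise ConfigError(
            f"pathway {pathway.name!r} oxidizes no H2; ATP per H2 undefined")
    return pathway.net_atp / pathway.h2_per_basis


def evaluate_pathway(pathway: Pathway, conditions: SiteConditions,
                     constants: ConstantsTable,
                     threshold: float = VIABILITY_THRESHOLD,
                     activity_model: str = "ideal") -> ViabilityReport:
    """Classify one pathway at one site against the energy threshold.

    The comparison is inclusive at exactly the threshold.  Divergent
    energies (zero concentrations) are classified explicitly: a zero
    reactant (ΔG → +∞) is non-viable, a zero product (ΔG → −∞) viable.
    """
    conditions = pathway.conditions_for(conditions)
    conditions = conditions.with_carbonate(constants, activity_model)
    energy = delta_g_in_situ(pathway.net_reaction, conditions, constants,
                             activity_model=activity_model)
    dg = energy.dG_insitu
    reason = ""
    if isinstance(dg, Unbounded):
        side = "reactant" if dg.direction > 0 else "product"
        sign = "+inf" if dg.direction > 0 else "-inf"
        reason = f"[{dg.species}] = 0 ({side}); dG unbounded ({sign})"
    elif pathway.atp_investment is not None:
        n, per = pathway.atp_investment
        dg = dg + n * per
        reason = f"includes {n} ATP invested at {per} kJ/mol"
    try:
        per_h2 = atp_per_h2(pathway)
    except ConfigError:
        per_h2 = None
    return ViabilityReport(pathway=pathway.name, dG_insitu=dg,
                           threshold=threshold, atp_per_h2=per_h2,
                           energy=energy, reason=reason)


def atp_invested_variant(base: Pathway, n_atp: int, atp_hydrolysis_dG: float,
                         conditions: SiteConditions,
                         constants: ConstantsTable,
                         threshold: float = VIABILITY_THRESHOLD,
                         activity_model: str = "ideal") -> ViabilityReport:
    """Evaluate ``base`` with ``n_atp`` ATP of up-front investment:
    dG = base dG + n_atp·ΔG_ATP, ledger extended by −n_atp."""
    variant = _apply_investment(base, f"{base.name}-{n_atp}ATP", n_atp,
                                atp_hydrolysis_dG) if n_atp else base
    return evaluate_pathway(variant, conditions, constants, threshold,
                            activity_model)


#: carrier couple midpoint potentials at pH 7 (V), ox/red activity ratio 1
DEFAULT_CARRIER_POTENTIALS = {
    "NADP+/NADPH": -0.320,
    "NAD+/NADH": -0.320,
    "Fd_ox/Fd_red": -0.420,
}


def donor_oxidation_favorability(donor: str, conditions: SiteConditions,
                                 constants: ConstantsTable,
                                 carriers: Optional[Mapping[str, float]] = None,
                                 ox_red_ratio: float = 1.0) -> Dict[str, float]:
    """ΔG (kJ per mol donor) of H2 or formate oxidation against each
    physiological electron carrier, plus the least-negative entry under
    the key ``"limiting"``.

    The donor half-couple potential is computed from the constants table
    and in situ activities (Nernst); carrier couples sit at their pH-7
    midpoints with a configurable ox/red activity ratio.
    """
    carriers = dict(carriers or DEFAULT_CARRIER_POTENTIALS)
    conditions = conditions.with_carbonate(constants)
    T = conditions.temperature
    rt_nf = R * T / (2 * F)
    h = conditions.proton_activity

    def conc(name: str) -> float:
        c = conditions.concentrations.get(name)
        if c is None or c <= 0:
            raise ConfigError(f"need a positive [{name}] for donor {donor!r}")
        return c

    if donor == "H2":
        # 2H+ + 2e- -> H2(aq); E0 from dGf(H2 aq)
        e0 = -constants["H2(aq)"].dGf298 / (2 * F)
        e_don = e0 - rt_nf * math.log(conc("H2(aq)") / (h * h))
    elif donor == "formate":
        # CO2(aq) + H+ + 2e- -> formate-
        dg_red = constants["formate"].dGf298 - constants["CO2(aq)"].dGf298
        e0 = -dg_red / (2 * F)
        e_don = e0 - rt_nf * math.log(
            conc("formate") / (conc("CO2(aq)") * h))
    else:
        raise ConfigError(f"unknown donor {donor!r} (use 'H2' or 'formate')")

    out: Dict[str, float] = {}
    for name, midpoint in carriers.items():
        e_acc = midpoint + rt_nf * math.log(ox_red_ratio)
        out[name] = -2 * F * (e_acc - e_don)
    out["limiting"] = max(v for k, v in out.items())
    return out


def sensitivity(pathway: Pathway, conditions: SiteConditions,
                species: str, delta: float,
                constants: ConstantsTable,
                activity_model: str = "ideal") -> float:
    """Finite-difference ΔΔG (kJ per mol basis) for a concentration
    perturbation ``delta`` (mol/L) of one participating species."""
    if species not in pathway.net_reaction.stoichiometry:
        raise ConfigError(
            f"{species!r} does not participate in pathway {pathway.name!r}")
    conditions = pathway.conditions_for(conditions)
    conditions = conditions.with_carbonate(constants, activity_model)
    base_conc = conditions.concentrations.get(species)
    if base_conc is None:
        raise ConfigError(f"no concentration for {species!r} at "
                          f"{conditions.site_name!r}")
    new_conc = base_conc + delta
    if new_conc <= 0:
        raise ConfigError(
            f"perturbation {delta} drives [{species}] to {new_conc} <= 0")
    base = delta_g_in_situ(pathway.net_reaction, conditions, constants,
                           activity_model=activity_model).dG_insitu
    pert = delta_g_in_situ(pathway.net_reaction,
                           conditions.with_concentrations({species: new_conc}),
                           constants, activity_model=activity_model).dG_insitu
    return pert - base
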