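"""Chemical species, reactions, and the packaged thermodynamic constants.

Species carry standard-state formation energetics at 298.15 K
(kJ/mol) plus an elemental composition and charge used for reaction
balance validation.  The constants table ships as a CSV inside the
package; several enthalpy rows are *calibrated* effective values (see
``docs/methods.md``) and are flagged as such in the ``source`` column.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Mapping, Optional

import pandas as pd

from .errors import BalanceError, MissingSpeciesError

#: Gas constant, kJ/(mol*K).
R = 8.314e-3
#: Reference temperature for the constants table, K.
T_REF = 298.15

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_PHASES = ("aqueous", "liquid-water", "gas")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a Hill-style formula string (e.g. ``C2H3O2``) into an
    element -> count map.  An empty string means a composition-free
    placeholder (used for abstract carriers such as thioredoxin)."""
    text = text.strip()
    counts: Dict[str, int] = {}
    if not text:
        return counts
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r}")
        el, n = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r}")
    return counts


@dataclass(frozen=True)
class ThermoSpecies:
    """One chemical species with formation energetics and composition."""

    name: str
    formula: Mapping[str, int]
    charge: int
    phase: str = "aqueous"
    dGf298: float = 0.0  # kJ/mol
    dHf298: float = 0.0  # kJ/mol
    molar_volume: Optional[float] = None  # cm^3/mol
    source: str = ""

    def __post_init__(self):
        if self.phase not in _PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        for el, n in self.formula.items():
            if not (isinstance(n, int) and n >= 0):
                raise ValueError(f"{self.name}: formula count {el}={n!r}")
        if not (math.isfinite(self.dGf298) and math.isfinite(self.dHf298)):
            raise ValueError(f"{self.name}: non-finite formation energetics")

    @property
    def is_water(self) -> bool:
        return self.phase == "liquid-water"


class ConstantsTable:
    """Lookup of :class:`ThermoSpecies` by name, plus equilibrium-constant
    rows (``pK``-style entries stored in the same CSV)."""

    def __init__(self, species: Iterable[ThermoSpecies],
                 equilibria: Optional[Mapping[str, tuple]] = None):
        self._species = {sp.name: sp for sp in species}
        #: name -> (pK at 298.15 K, dH of dissociation kJ/mol)
        self.equilibria: Dict[str, tuple] = dict(equilibria or {})

    def __contains__(self, name: str) -> bool:
        return name in self._species

    def __getitem__(self, name: str) -> ThermoSpecies:
        try:
            return self._species[name]
        except KeyError:
            raise MissingSpeciesError(name) from None

    def __iter__(self):
        return iter(self._species.values())

    def __len__(self) -> int:
        return len(self._species)

    def names(self):
        return list(self._species)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ConstantsTable":
        df = pd.read_csv(path_or_buf, comment="#")
        required = {"species", "formula", "charge", "phase",
                    "dGf_kJ_mol", "dHf_kJ_mol"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"constants CSV missing columns: {sorted(missing)}")
        species = []
        equilibria = {}
        for row in df.itertuples(index=False):
            if row.phase == "equilibrium":
                # pK stored in the dGf column, dissociation enthalpy in dHf.
                equilibria[row.species] = (float(row.dGf_kJ_mol),
                                           float(row.dHf_kJ_mol))
                continue
            mv = getattr(row, "molar_volume_cm3_mol", None)
            mv = None if mv is None or pd.isna(mv) else float(mv)
            species.append(ThermoSpecies(
                name=row.species,
                formula=parse_formula(str(row.formula) if pd.notna(row.formula) else ""),
                charge=int(row.charge),
                phase=row.phase,
                dGf298=float(row.dGf_kJ_mol),
                dHf298=float(row.dHf_kJ_mol),
                molar_volume=mv,
                source=str(getattr(row, "source", "")),
            ))
        return cls(species, equilibria)


def load_constants() -> ConstantsTable:
    """Load the packaged constants table."""
    ref = resources.files("serplith.data").joinpath("constants.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return ConstantsTable.from_csv(fh)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric map over species names.

    Products carry positive coefficients, reactants negative.  Every
    energy the package reports is per mole of ``basis_species``.
    """

    name: str
    stoichiometry: Mapping[str, float]
    basis_species: str

    def __post_init__(self):
        if self.basis_species not in self.stoichiometry or \
                self.stoichiometry[self.basis_species] == 0:
            raise ValueError(
                f"{self.name}: basis species {self.basis_species!r} must "
                "appear with a nonzero coefficient")

    @property
    def basis_coefficient(self) -> float:
        return abs(self.stoichiometry[self.basis_species])

    def validate_balance(self, constants: ConstantsTable,
                         tol: float = 1e-9) -> None:
        """Raise :class:`BalanceError` listing every element/charge
        imbalance; raise :class:`MissingSpeciesError` for unknown species."""
        elements: Dict[str, float] = {}
        charge = 0.0
        for name, coeff in self.stoichiometry.items():
            sp = constants[name]
            charge += coeff * sp.charge
            for el, n in sp.formula.items():
                elements[el] = elements.get(el, 0.0) + coeff * n
        problems = [f"{el}: {bal:+g}" for el, bal in sorted(elements.items())
                    if abs(bal) > tol]
        if abs(charge) > tol:
            problems.append(f"charge: {charge:+g}")
        if problems:
            raise BalanceError(
                f"reaction {self.name!r} is unbalanced ({', '.join(problems)})")

    def reversed(self) -> "Reaction":
        return Reaction(
            name=f"reverse({self.name})",
            stoichiometry={s: -c for s, c in self.stoichiometry.items()},
            basis_species=self.basis_species,
        )

    def combined(self, other: "Reaction", name: str = "",
                 basis_species: Optional[str] = None) -> "Reaction":
        """Stoichiometric sum of two reactions (species-wise)."""
        st: Dict[str, float] = dict(self.stoichiometry)
        for s, c in other.stoichiometry.items():
            st[s] = st.get(s, 0.0) + c
        st = {s: c for s, c in st.items() if c != 0}
        return Reaction(name or f"{self.name}+{other.name}", st,
                        basis_species or self.basis_species)
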