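"""Site geochemistry state (temperature, pH, pressure, concentrations).

A :class:`SiteConditions` is one habitat's snapshot.  Concentrations are
molar; the proton activity is always derived from pH (never stored as a
concentration) and liquid water always has unit activity.  Total
inorganic carbon travels under the key ``TIC`` and can be expanded into
CO2(aq)/HCO3-/CO3^2- with :meth:`SiteConditions.with_carbonate`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import yaml

from .errors import ConfigError

#: key for total inorganic carbon in concentration maps
TIC_KEY = "TIC"


@dataclass(frozen=True)
class SiteConditions:
    site_name: str
    temperature: float          # K
    pH: float
    pressure: float = 1.0       # bar
    ionic_strength: float = 0.0  # mol/L
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigError(f"{self.site_name}: temperature must be > 0 K")
        if not (0.0 <= self.pH <= 14.0):
            raise ConfigError(f"{self.site_name}: pH {self.pH} outside [0, 14]")
        if self.ionic_strength < 0:
            raise ConfigError(f"{self.site_name}: negative ionic strength")
        if "H+" in self.concentrations:
            raise ConfigError(
                f"{self.site_name}: H+ is derived from pH, do not list it "
                "as a concentration")
        for sp, c in self.concentrations.items():
            if c < 0:
                raise ConfigError(f"{self.site_name}: [{sp}] = {c} < 0")

    @property
    def proton_activity(self) -> float:
        return 10.0 ** (-self.pH)

    def replace(self, **changes) -> "SiteConditions":
        return dataclasses.replace(self, **changes)

    def with_concentrations(self, updates: Mapping[str, float]) -> "SiteConditions":
        conc = dict(self.concentrations)
        conc.update(updates)
        return self.replace(concentrations=conc)

    def with_carbonate(self, constants, activity_model: str = "ideal") -> "SiteConditions":
        """Return a copy with CO2(aq)/HCO3-/CO3^2- derived from TIC.

        No-op if the conditions already carry CO2(aq) explicitly or have
        no TIC entry.
        """
        if "CO2(aq)" in self.concentrations or TIC_KEY not in self.concentrations:
            return self
        from .carbonate import speciate  # local import avoids a cycle
        state = speciate(self.pH, self.concentrations[TIC_KEY],
                         self.temperature, self.ionic_strength,
                         activity_model=activity_model, constants=constants)
        return self.with_concentrations({
            "CO2(aq)": state.co2_aq,
            "HCO3-": state.hco3,
            "CO3^2-": state.co3,
        })

    @classmethod
    def from_dict(cls, d: Mapping) -> "SiteConditions":
        try:
            return cls(
                site_name=str(d["site"]),
                temperature=float(d["temperature_C"]) + 273.15,
                pH=float(d["pH"]),
                pressure=float(d.get("pressure_bar", 1.0)),
                ionic_strength=float(d.get("ionic_strength_M", 0.0)),
                concentrations={str(k): float(v)
                                for k, v in (d.get("concentrations") or {}).items()},
            )
        except KeyError as exc:
            raise ConfigError(f"site config missing key {exc.args[0]!r}") from exc

    @classmethod
    def from_yaml(cls, path) -> "SiteConditions":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


def load_site(name_or_path: str) -> SiteConditions:
    """Load a site config: a packaged fixture name (``hakuba``/``cedars``)
    or a path to a YAML file."""
    from importlib import resources
    pkg_sites = resources.files("serplith.data").joinpath("sites")
    candidate = pkg_sites.joinpath(f"{name_or_path}.yaml")
    if candidate.is_file():
        with candidate.open("r", encoding="utf-8") as fh:
            return SiteConditions.from_dict(yaml.safe_load(fh))
    return SiteConditions.from_yaml(name_or_path)
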