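"""Full-report generation: the packaged Hakuba/Cedars analysis as TSVs.

Reports are deterministic byte-for-byte given identical inputs: all
numbers use fixed decimal formatting, units live in the headers, and no
timestamps enter data files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .carbonate import speciate
from .conditions import SiteConditions, load_site
from .errors import ConfigError
from .pathways import (VIABILITY_THRESHOLD, atp_per_h2, evaluate_pathway,
                       load_pathways, sensitivity)
from .species import ConstantsTable, load_constants
from .thermo import Unbounded

__all__ = ["RunConfig", "run_full_report"]

_PATHWAY_ORDER = [
    "h2_co2_acetogenesis", "h2_formate_acetogenesis",
    "formate_disproportionation", "glycine_reduction",
    "cbb_h2_co2", "rtca_h2_co2",
]


@dataclass
class RunConfig:
    """Inputs for :func:`run_full_report`.

    Defaults reproduce the packaged Hakuba/Cedars analysis without any
    flags: packaged constants, packaged pathway registry, both site
    fixtures, ideal activity model, −20 kJ/mol threshold.
    """

    sites: Sequence[str] = ("hakuba", "cedars")
    constants_path: Optional[str] = None
    activity_model: str = "ideal"
    speciation_activity_model: str = "davies"
    threshold: float = VIABILITY_THRESHOLD
    out_dir: str = "results"

    def load_constants(self) -> ConstantsTable:
        if self.constants_path is None:
            return load_constants()
        if not os.path.exists(self.constants_path):
            raise ConfigError(
                f"constants file not found: {self.constants_path}")
        return ConstantsTable.from_csv(self.constants_path)

    def load_sites(self) -> List[SiteConditions]:
        out = []
        for s in self.sites:
            try:
                out.append(load_site(s))
            except FileNotFoundError as exc:
                raise ConfigError(f"site config not found: {s}") from exc
        return out


def _fmt_dg(dg) -> str:
    if isinstance(dg, Unbounded):
        return "+inf" if dg.direction > 0 else "-inf"
    return f"{dg:.2f}"


def run_full_report(config: RunConfig) -> dict:
    """Write the four report tables and return their paths.

    Tables: (1) carbonate speciation per site, (2) pathway viability per
    site, (3) ATP-per-H2 comparison, (4) H2 sensitivity per site.
    """
    constants = config.load_constants()
    sites = config.load_sites()
    pathways = load_pathways(constants)
    order = [n for n in _PATHWAY_ORDER if n in pathways] + \
        sorted(set(pathways) - set(_PATHWAY_ORDER))
    os.makedirs(config.out_dir, exist_ok=True)
    paths = {}

    lines = ["site\tpH\ttemperature_K\tTIC_M\tCO2_aq_M\tHCO3_M\tCO3_M\t"
             "x_CO2\tx_HCO3\tx_CO3"]
    for site in sites:
        tic = site.concentrations.get("TIC", 0.0)
        st = speciate(site.pH, tic, site.temperature, site.ionic_strength,
                      config.speciation_activity_model, constants)
        lines.append(
            f"{site.site_name}\t{site.pH:.2f}\t{site.temperature:.2f}\t"
            f"{tic:.3e}\t{st.co2_aq:.4e}\t{st.hco3:.4e}\t{st.co3:.4e}\t"
            f"{st.fractions[0]:.4e}\t{st.fractions[1]:.4e}\t"
            f"{st.fractions[2]:.4e}")
    paths["speciation"] = _write(config.out_dir, "speciation.tsv", lines)

    lines = ["site\tpathway\tdG0_298_kJ_mol\tdG0_T_kJ_mol\tRTlnQ_kJ_mol\t"
             "dG_insitu_kJ_mol\tviable\tatp_per_h2"]
    for site in sites:
        for name in order:
            rep = evaluate_pathway(pathways[name], site, constants,
                                   config.threshold, config.activity_model)
            e = rep.energy
            per_h2 = "" if rep.atp_per_h2 is None else f"{rep.atp_per_h2:.3f}"
            lines.append(
                f"{site.site_name}\t{name}\t{e.dG0_298:.2f}\t{e.dG0_T:.2f}\t"
                f"{_fmt_dg(e.rt_lnQ)}\t{_fmt_dg(rep.dG_insitu)}\t"
                f"{str(rep.viable).lower()}\t{per_h2}")
    paths["energetics"] = _write(config.out_dir, "energetics.tsv", lines)

    lines = ["pathway\tnet_atp_per_basis\th2_per_basis\tatp_per_h2"]
    for name in order:
        pw = pathways[name]
        if pw.h2_per_basis > 0:
            lines.append(f"{name}\t{pw.net_atp:.3f}\t{pw.h2_per_basis:g}\t"
                         f"{atp_per_h2(pw):.3f}")
    paths["atp_comparison"] = _write(config.out_dir, "atp_comparison.tsv",
                                     lines)

    lines = ["site\tpathway\tspecies\tdelta_M\tddG_kJ_mol"]
    for site in sites:
        for name in order:
            pw = pathways[name]
            if "H2(aq)" not in pw.net_reaction.stoichiometry:
                continue
            ddg = sensitivity(pw, site, "H2(aq)", -20e-6, constants,
                              config.activity_model)
            lines.append(f"{site.site_name}\t{name}\tH2(aq)\t-2.000e-05\t"
                         f"{ddg:.3f}")
    paths["sensitivity"] = _write(config.out_dir, "sensitivity.tsv", lines)
    return paths


def _write(out_dir: str, fname: str, lines: List[str]) -> str:
    path = os.path.join(out_dir, fname)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
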