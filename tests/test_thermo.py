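"""Standard, temperature-adjusted, and in situ reaction energies."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import serplith as sp
from serplith.errors import ConfigError, MissingConcentrationError
from serplith.species import R, T_REF
from serplith.thermo import Unbounded

WLP = sp.Reaction("h2_co2", {"H2(aq)": -4, "CO2(aq)": -2, "acetate": 1,
                             "H+": 1, "H2O": 2}, "acetate")
FDISP = sp.Reaction("fdisp", {"formate": -4, "H+": -3, "acetate": 1,
                              "CO2(aq)": 2, "H2O": 2}, "acetate")


def conds(**kw):
    defaults = dict(site_name="toy", temperature=T_REF, pH=7.0,
                    concentrations={})
    defaults.update(kw)
    return sp.SiteConditions(**defaults)


class TestStandardReactionEnergy:
    def test_h2_co2_acetogenesis(self, constants):
        # hand sum of the packaged dGf column: -142.69 kJ/mol acetate
        assert sp.standard_reaction_energy(WLP, constants) == \
            pytest.approx(-142.69, abs=1e-9)

    def test_formate_disproportionation(self, constants):
        assert sp.standard_reaction_energy(FDISP, constants) == \
            pytest.approx(-211.57, abs=1e-9)

    def test_per_basis_normalization(self, constants):
        doubled = sp.Reaction("x2", {s: 2 * c for s, c in
                                     WLP.stoichiometry.items()}, "acetate")
        assert sp.standard_reaction_energy(doubled, constants) == \
            pytest.approx(sp.standard_reaction_energy(WLP, constants))


class TestGibbsHelmholtz:
    def test_identity_at_reference_temperature(self):
        assert sp.gibbs_helmholtz_adjust(-10.0, -20.0, 298.15) == -10.0

    def test_zero_enthalpy_scales_linearly(self):
        assert sp.gibbs_helmholtz_adjust(-10.0, 0.0, 2 * 298.15) == \
            pytest.approx(-20.0)

    def test_against_closed_form(self):
        # frozen one-line evaluation: -142.6*(321.15/298.15) - 250*(1-321.15/298.15)
        assert sp.gibbs_helmholtz_adjust(-142.6, -250.0, 321.15) == \
            pytest.approx(-134.31490860305215, abs=1e-9)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ConfigError):
            sp.gibbs_helmholtz_adjust(-1.0, -1.0, 0.0)

    @given(st.floats(-500, 500), st.floats(-800, 800),
           st.floats(10, 600), st.floats(10, 600), st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_linear_in_temperature(self, g, h, t1, t2, w):
        tm = w * t1 + (1 - w) * t2
        f1 = sp.gibbs_helmholtz_adjust(g, h, t1)
        f2 = sp.gibbs_helmholtz_adjust(g, h, t2)
        assert sp.gibbs_helmholtz_adjust(g, h, tm) == \
            pytest.approx(w * f1 + (1 - w) * f2, abs=1e-6)


class TestReactionQuotient:
    def test_unit_activities_give_zero(self, constants):
        c = conds(pH=0.0, concentrations={"H2(aq)": 1.0, "CO2(aq)": 1.0,
                                          "acetate": 1.0})
        assert sp.reaction_quotient_term(WLP, c, constants) == \
            pytest.approx(0.0, abs=1e-12)

    def test_toy_concentration_ratio(self, constants):
        # glycine -> glycinate + H+ has a single-species-each quotient;
        # simpler: use acetate production only via a 1:1 toy
        rxn = sp.Reaction("toy", {"glycine": -1, "glycinate": 1, "H+": 1},
                          "glycine")
        c = conds(pH=0.0, concentrations={"glycine": 1e-3, "glycinate": 1e-6})
        # RT ln(1e-6/1e-3) frozen: -17.123075723666748
        assert sp.reaction_quotient_term(rxn, c, constants) == \
            pytest.approx(-17.123075723666748, abs=1e-9)

    def test_missing_concentration_is_loud(self, constants):
        c = conds(concentrations={"H2(aq)": 1e-6, "CO2(aq)": 1e-6})
        with pytest.raises(MissingConcentrationError, match="acetate"):
            sp.reaction_quotient_term(WLP, c, constants)

    def test_zero_reactant_tagged_positive_unbounded(self, constants):
        c = conds(concentrations={"H2(aq)": 0.0, "CO2(aq)": 1e-6,
                                  "acetate": 1e-6})
        out = sp.reaction_quotient_term(WLP, c, constants)
        assert isinstance(out, Unbounded)
        assert out.direction == +1 and out.species == "H2(aq)"

    def test_zero_product_tagged_negative_unbounded(self, constants):
        c = conds(concentrations={"H2(aq)": 1e-6, "CO2(aq)": 1e-6,
                                  "acetate": 0.0})
        out = sp.reaction_quotient_term(WLP, c, constants)
        assert isinstance(out, Unbounded) and out.direction == -1

    def test_hakuba_quotient_dominated_by_co2(self, constants, hakuba):
        full = hakuba.with_carbonate(constants)
        term = sp.reaction_quotient_term(WLP, full, constants)
        assert term > 0
        # the CO2^-2 factor alone contributes most of the term
        co2_part = -2 * R * full.temperature * \
            math.log(full.concentrations["CO2(aq)"])
        assert co2_part > 0.5 * term


class TestBiochemicalStandard:
    def test_no_protons_means_no_shift(self, constants):
        rxn = sp.Reaction("hyd", {"H2(aq)": -1, "H2(g)": 1}, "H2(g)")
        assert sp.biochemical_standard(rxn, constants) == \
            pytest.approx(sp.standard_reaction_energy(rxn, constants))

    def test_one_proton_produced_shifts_down(self, constants):
        dg0 = sp.standard_reaction_energy(WLP, constants)
        # frozen RT ln 1e-7 at 298.15 K
        assert sp.biochemical_standard(WLP, constants) == \
            pytest.approx(dg0 - 39.95384335522242, abs=1e-9)


class TestPressure:
    def test_disabled_returns_unchanged(self, constants):
        assert sp.pressure_adjust(-10.0, WLP, 500.0, constants) == -10.0

    def test_one_bar_is_identity_when_enabled(self, constants):
        assert sp.pressure_adjust(-10.0, WLP, 1.0, constants,
                                  enabled=True) == -10.0

    def test_linear_volume_term(self, constants):
        # dV = -20 cm3/mol at 101 bar: -20 * 100 bar * 1e-4 = -0.2 kJ/mol
        rxn = sp.Reaction("vol", {"H2(aq)": -1, "H2(g)": 1}, "H2(g)")
        table = sp.ConstantsTable([
            sp.ThermoSpecies("H2(aq)", {"H": 2}, 0, "aqueous", 17.72, -4.2,
                             molar_volume=25.0),
            sp.ThermoSpecies("H2(g)", {"H": 2}, 0, "gas", 0.0, 0.0,
                             molar_volume=5.0),
        ])
        assert sp.pressure_adjust(-10.0, rxn, 101.0, table, enabled=True) == \
            pytest.approx(-10.2)

    def test_enabled_without_volumes_is_config_error(self, constants):
        # packaged H2(g) row has no molar volume
        rxn = sp.Reaction("hyd", {"H2(aq)": -1, "H2(g)": 1}, "H2(g)")
        with pytest.raises(ConfigError, match="molar volume"):
            sp.pressure_adjust(0.0, rxn, 2.0, constants, enabled=True)


class TestDeltaGInSitu:
    def test_unit_activities_at_reference_t_equal_standard(self, constants):
        c = conds(pH=0.0, concentrations={"H2(aq)": 1.0, "CO2(aq)": 1.0,
                                          "acetate": 1.0})
        e = sp.delta_g_in_situ(WLP, c, constants)
        assert e.dG_insitu == pytest.approx(e.dG0_298, abs=1e-9)
        assert e.dG0_T == pytest.approx(e.dG0_298)

    def test_additivity_is_definitional(self, constants, hakuba):
        e = sp.delta_g_in_situ(WLP, hakuba, constants)
        assert e.dG_insitu == e.dG0_T + e.rt_lnQ + e.pressure_term

    def test_reversal_negates_every_field(self, constants, hakuba):
        f = sp.delta_g_in_situ(WLP, hakuba, constants)
        b = sp.delta_g_in_situ(WLP.reversed(), hakuba, constants)
        for attr in ("dG0_298", "dG0_T", "rt_lnQ", "dG_insitu"):
            assert getattr(b, attr) == pytest.approx(-getattr(f, attr),
                                                     abs=1e-9)

    def test_total_energy_additive_over_reaction_sum(self, constants, hakuba,
                                                     registry):
        r1 = registry["h2_co2_acetogenesis"].net_reaction
        r2 = registry["glycine_reduction"].net_reaction
        r3 = r1.combined(r2, name="sum", basis_species="acetate")
        full = hakuba.with_carbonate(constants)

        def total(rxn):
            e = sp.delta_g_in_situ(rxn, full, constants)
            return e.dG_insitu * rxn.basis_coefficient

        assert total(r3) == pytest.approx(total(r1) + total(r2), abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_one_expression_oracle(self, constants, seed):
        """delta_g_in_situ == (Σν·Gf)·(T/T0) + (Σν·Hf)·(1−T/T0) + RT·Σν·ln a
        on randomized conditions, evaluated independently here."""
        import numpy as np
        rng = np.random.default_rng(seed)
        temp = float(rng.uniform(274.0, 370.0))
        ph = float(rng.uniform(2.0, 13.0))
        concs = {name: float(np.exp(rng.uniform(np.log(1e-9), np.log(1e-1))))
                 for name in ("H2(aq)", "CO2(aq)", "formate", "acetate",
                              "glycine", "NH3(aq)")}
        c = conds(temperature=temp, pH=ph, concentrations=concs)
        rxn = FDISP if seed % 2 else WLP
        got = sp.delta_g_in_situ(rxn, c, constants).dG_insitu
        g = sum(v * constants[s].dGf298 for s, v in rxn.stoichiometry.items())
        h = sum(v * constants[s].dHf298 for s, v in rxn.stoichiometry.items())
        lnq = 0.0
        for s, v in rxn.stoichiometry.items():
            if s == "H2O":
                continue
            a = 10 ** (-ph) if s == "H+" else concs[s]
            lnq += v * math.log(a)
        expect = (g * (temp / T_REF) + h * (1 - temp / T_REF)
                  + R * temp * lnq) / abs(rxn.stoichiometry["acetate"])
        assert got == pytest.approx(expect, abs=1e-9)
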