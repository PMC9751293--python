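"""How hyperalkaline pH starves autotrophs of CO2.

Partitions total inorganic carbon at the two springs' pH/temperature
and prints the equilibrium CO2(aq) concentration, then the carbonate
level calcite precipitation would require.  The CO2 numbers are in the
sub-nanomolar range, around a million times lower than circumneutral
freshwater, which is the core constraint on CO2-reducing metabolism in
these systems.
"""

import serplith as sp

constants = sp.load_constants()
for name in ("hakuba", "cedars"):
    site = sp.load_site(name)
    st = sp.speciate(site.pH, site.concentrations["TIC"], site.temperature,
                     site.ionic_strength, "davies", constants)
    print(f"{name}: pH {site.pH}, TIC {site.concentrations['TIC']:.1e} M"
          f" -> CO2(aq) = {st.co2_aq * 1e9:.4f} nM"
          f" (CO2:HCO3:CO3 fractions {st.fractions[0]:.2e},"
          f" {st.fractions[1]:.3f}, {st.fractions[2]:.3f})")

res = sp.saturation_threshold(Ks=5e-9, cation=0.13e-3, co3=84.7e-9)
print(f"\ncalcite threshold at [Ca2+] = 0.13 mM: "
      f"{res.threshold * 1e6:.1f} uM CO3^2-")
print(f"in situ carbonate 84.7 nM -> saturated: {res.saturated}")
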